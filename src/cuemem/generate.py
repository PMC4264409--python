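"""Synthetic word-by-word self-paced-reading data.

Generates long-format reading-time tables with the statistical structure of
two factorial sentence-comprehension designs:

* a 2x2 complexity design — matrix subject (NP1) and matrix object (NP2,
  the downstream retrieval target) each carry 0 or 2 prenominal modifiers,
  with the object modified by an object relative clause, so the embedded
  verb triggers retrieval of NP2 (default 52 participants, 28 items, 70
  fillers);
* a 2x2 colour-congruence design — the object head noun and the
  retrieval-triggering verb each appear congruently (white) or
  incongruently (green) coloured (default 44 participants, 32 items,
  60 fillers).

Per-word log reading times are a sum of a grand mean, a word-length
effect, a log-list-position practice effect, participant/item random
effects (intercepts plus condition slopes), region offsets, an encoding
cost at the manipulated word, a retrieval cost at the embedded verb, and
Gaussian noise, exponentiated to milliseconds.  The retrieval cost is
surprisal-style, ``kappa * (-log p_target)``, with the per-condition target
sampling probability delivered by the cue-redintegration model in
:mod:`cuemem.sentences` — so encoding interference propagates all the way
into simulated reading times.  A small contamination rate draws words from
an extreme-RT tail to exercise outlier trimming downstream.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .sentences import EncodingConfig, InterferenceParams, predict_conditions

__all__ = [
    "GeneratorParams",
    "REGIONS",
    "DATASET_COLUMNS",
    "generate_exp1",
    "generate_exp2",
    "write_dataset",
    "read_dataset",
]

REGIONS = ("NP2_head", "NP3_head", "NP3_head+1", "RC_verb", "RC_verb+1", "other")

DATASET_COLUMNS = [
    "participant",
    "item",
    "condition",
    "is_filler",
    "list_position",
    "word_index",
    "word",
    "word_length",
    "region",
    "rt_ms",
    "question_correct",
]

_COLUMN_DTYPES = {
    "participant": "int64",
    "item": "int64",
    "condition": "object",
    "is_filler": "bool",
    "list_position": "int64",
    "word_index": "int64",
    "word": "object",
    "word_length": "int64",
    "region": "object",
    "rt_ms": "float64",
    "question_correct": "bool",
}


@dataclass(frozen=True)
class GeneratorParams:
    """All effect sizes, random-effect SDs and linkage parameters.

    Log-RT scale throughout (natural log of milliseconds).  The defaults
    emulate the complexity experiment: 52 participants, 28 critical items
    in a four-list Latin square, 70 fillers, overall question accuracy
    0.84, and condition effects at the verb in the few-hundredths-of-a-
    log-unit range typical of self-paced-reading residual analyses.
    """

    n_participants: int = 52
    n_items: int = 28
    n_fillers: int = 70
    #: grand mean log RT; exp(5.75) ~ 314 ms per word
    mu_log_rt: float = 5.75
    #: slowdown per character of word length
    beta_length: float = 0.02
    #: practice speed-up per unit log list position (negative = faster later)
    beta_logpos: float = -0.04
    sd_participant_intercept: float = 0.15
    sd_participant_slope: float = 0.02
    sd_item_intercept: float = 0.05
    sd_item_slope: float = 0.01
    #: residual SD of log RT (lognormal trial noise)
    sd_residual: float = 0.22
    #: encoding cost per additional target feature, applied at the
    #: manipulated word (modified NP head / incongruently coloured word)
    encoding_cost: float = 0.04
    #: retrieval linkage: log-RT cost per unit -log(target sampling
    #: probability) at the embedded verb
    kappa: float = 0.28
    #: fraction of the retrieval cost carried into the verb's spillover
    #: word; the spillover effect is empirically as strong as at the verb
    carryover: float = 1.0
    #: per-region additive offsets on log RT (unlisted regions: 0)
    region_offsets: tuple[tuple[str, float], ...] = ()
    #: fraction of words drawn from an extreme-RT tail (exercises trimming)
    contamination_rate: float = 0.001
    #: probability a comprehension question is answered correctly
    accuracy: float = 0.84
    #: feature-overwriting probability fed to the interference model
    overwrite_probability: float = 0.3
    #: Monte-Carlo replicates for the per-condition retrieval probability
    interference_reps: int = 2000
    # colour-design effects (second experiment only)
    noun_color_cost: float = 0.08
    verb_color_cost: float = 0.06
    #: optional noun-by-verb colour interaction at the verb (reinstatement
    #: of encoding-phase features at retrieval); 0 = the null finding
    reinstatement: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_items, self.n_fillers) < 1:
            raise ValueError("participant/item/filler counts must be >= 1")
        sds = (
            self.sd_participant_intercept,
            self.sd_participant_slope,
            self.sd_item_intercept,
            self.sd_item_slope,
            self.sd_residual,
        )
        if any(s < 0 for s in sds):
            raise ValueError("random-effect and residual SDs must be >= 0")
        if not 0.0 <= self.carryover <= 1.0:
            raise ValueError("carryover must lie in [0, 1]")
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ValueError("contamination_rate must lie in [0, 1]")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")

    @classmethod
    def exp2(cls, **overrides) -> "GeneratorParams":
        """Defaults for the colour-congruence design: 44 participants,
        32 items, 60 fillers."""
        base = dict(n_participants=44, n_items=32, n_fillers=60)
        base.update(overrides)
        return cls(**base)

    def region_offset(self, region: str) -> float:
        return dict(self.region_offsets).get(region, 0.0)


# ---------------------------------------------------------------------------
# Retrieval linkage
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _condition_retrieval_probs(
    overwrite_probability: float, n_reps: int, seed: int
) -> dict[str, float]:
    """Per-condition target sampling probabilities from the memory model.

    Cached: the linkage depends only on the interference settings, not on
    the reading-time noise, so repeated dataset replicates share it.
    """
    preds = predict_conditions(
        params=InterferenceParams(
            overwrite_probability=overwrite_probability,
            n_reps=n_reps,
            seed=seed,
        ),
        config=EncodingConfig(),
    )
    return {p.condition: p.target_probability for p in preds}


# ---------------------------------------------------------------------------
# Sentence templates
# ---------------------------------------------------------------------------

_LETTERS = np.array(list(string.ascii_lowercase))


def _random_word(rng: np.random.Generator, lo: int = 4, hi: int = 10) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(_LETTERS, size=n))


def _item_lexicon(rng: np.random.Generator) -> dict[str, str]:
    """Content words for one item; shared across its conditions."""
    return {
        "np1_head": _random_word(rng, 5, 10),
        "np1_mod1": _random_word(rng, 4, 9),
        "np1_mod2": _random_word(rng, 4, 9),
        "matrix_verb": _random_word(rng, 5, 11),
        "np2_head": _random_word(rng, 5, 10),
        "np2_mod1": _random_word(rng, 4, 9),
        "np2_mod2": _random_word(rng, 4, 9),
        "np3_head": _random_word(rng, 5, 10),
        "pp_noun": _random_word(rng, 5, 10),
        "rc_verb": _random_word(rng, 5, 11),
        "final1": _random_word(rng, 4, 9),
        "final2": _random_word(rng, 4, 9),
        "final3": _random_word(rng, 4, 9),
    }


def _exp1_sentence(
    lex: dict[str, str], np1_complex: bool, np2_complex: bool
) -> list[tuple[str, str]]:
    """(word, region) sequence for one condition of a complexity item."""
    words: list[tuple[str, str]] = [("the", "other")]
    if np1_complex:
        words += [(lex["np1_mod1"], "other"), (lex["np1_mod2"], "other")]
    words += [
        (lex["np1_head"], "other"),
        (lex["matrix_verb"], "other"),
        ("the", "other"),
    ]
    if np2_complex:
        words += [(lex["np2_mod1"], "other"), (lex["np2_mod2"], "other")]
    words += [
        (lex["np2_head"], "NP2_head"),
        ("who", "other"),
        ("the", "other"),
        (lex["np3_head"], "NP3_head"),
        ("for", "NP3_head+1"),
        ("the", "other"),
        (lex["pp_noun"], "other"),
        (lex["rc_verb"], "RC_verb"),
        ("to", "RC_verb+1"),
        (lex["final1"], "other"),
        (lex["final2"], "other"),
        (lex["final3"], "other"),
    ]
    return words


def _exp2_sentence(lex: dict[str, str]) -> list[tuple[str, str]]:
    """Colour items are textually identical across conditions."""
    return _exp1_sentence(lex, np1_complex=False, np2_complex=False)


_EXP1_CONDITIONS = (
    "simple-simple",
    "simple-complex",
    "complex-simple",
    "complex-complex",
)
_EXP2_CONDITIONS = (
    "white-white",
    "white-green",
    "green-white",
    "green-green",
)


# ---------------------------------------------------------------------------
# Core generator
# ---------------------------------------------------------------------------


def _condition_contrasts(condition: str, conditions: tuple[str, ...]) -> np.ndarray:
    """Sum-coded (+1 second level) contrast triple (A, B, AxB)."""
    a, b = condition.split("-")
    levels_a = sorted({c.split("-")[0] for c in conditions})
    xa = -1.0 if a == levels_a[0] else 1.0
    levels_b = sorted({c.split("-")[1] for c in conditions})
    xb = -1.0 if b == levels_b[0] else 1.0
    return np.array([xa, xb, xa * xb])


def _generate(params: GeneratorParams, experiment: int) -> pd.DataFrame:
    rng = np.random.default_rng(params.seed)
    conditions = _EXP1_CONDITIONS if experiment == 1 else _EXP2_CONDITIONS

    retrieval_cost: dict[str, float] = {}
    if experiment == 1:
        p_target = _condition_retrieval_probs(
            params.overwrite_probability, params.interference_reps, params.seed
        )
        # condition labels are NP1-NP2; the retrieval model uses the same keys
        retrieval_cost = {
            c: params.kappa * (-math.log(p_target[c])) for c in conditions
        }

    # item structures (shared across participants)
    item_lex = [_item_lexicon(rng) for _ in range(params.n_items)]
    filler_words = [
        [(_random_word(rng, 2, 11), "other") for _ in range(int(rng.integers(8, 15)))]
        for _ in range(params.n_fillers)
    ]

    # random effects
    b_part = rng.normal(0.0, params.sd_participant_intercept, params.n_participants)
    s_part = rng.normal(
        0.0, params.sd_participant_slope, (params.n_participants, 3)
    )
    b_item = rng.normal(0.0, params.sd_item_intercept, params.n_items)
    s_item = rng.normal(0.0, params.sd_item_slope, (params.n_items, 3))

    rows: list[tuple] = []
    n_trials = params.n_items + params.n_fillers
    for p in range(params.n_participants):
        trial_ids = list(range(n_trials))  # 0..n_items-1 critical, rest filler
        rng.shuffle(trial_ids)
        for pos, tid in enumerate(trial_ids, start=1):
            is_filler = tid >= params.n_items
            item = tid  # filler ids continue after critical item ids
            correct = bool(rng.random() < params.accuracy)
            practice = params.beta_logpos * math.log(pos)
            np2_c = noun_green = verb_green = False
            if is_filler:
                condition = "filler"
                words = filler_words[tid - params.n_items]
                trial_re = b_part[p]
            else:
                # four-list Latin square: participant p's list assigns item
                # i condition (i + p) mod 4
                condition = conditions[(tid + p) % 4]
                x = _condition_contrasts(condition, conditions)
                trial_re = b_part[p] + b_item[item] + x @ (s_part[p] + s_item[item])
                if experiment == 1:
                    np1_c, np2_c = (lvl == "complex" for lvl in condition.split("-"))
                    words = _exp1_sentence(item_lex[item], np1_c, np2_c)
                else:
                    words = _exp2_sentence(item_lex[item])
                    noun_green, verb_green = (
                        lvl == "green" for lvl in condition.split("-")
                    )
            for w_idx, (word, region) in enumerate(words, start=1):
                mu = (
                    params.mu_log_rt
                    + params.beta_length * len(word)
                    + practice
                    + trial_re
                    + params.region_offset(region)
                )
                if not is_filler:
                    if experiment == 1:
                        if region == "NP2_head" and np2_c:
                            # 2 modifiers x 1 unique feature each
                            mu += params.encoding_cost * 2
                        elif region == "RC_verb":
                            mu += retrieval_cost[condition]
                        elif region == "RC_verb+1":
                            mu += params.carryover * retrieval_cost[condition]
                    else:
                        if region == "NP2_head" and noun_green:
                            mu += params.noun_color_cost
                        elif region == "RC_verb":
                            if verb_green:
                                mu += params.verb_color_cost
                            if noun_green and verb_green:
                                mu += params.reinstatement
                log_rt = mu + rng.normal(0.0, params.sd_residual)
                rt = math.exp(log_rt)
                if rng.random() < params.contamination_rate:
                    # extreme tail: always outside the standard trim bounds
                    if rng.random() < 0.5:
                        rt = float(rng.uniform(20.0, 90.0))
                    else:
                        rt = float(rng.uniform(5500.0, 30000.0))
                rows.append(
                    (
                        p,
                        item,
                        condition,
                        is_filler,
                        pos,
                        w_idx,
                        word,
                        len(word),
                        region,
                        rt,
                        correct,
                    )
                )

    return pd.DataFrame(rows, columns=DATASET_COLUMNS).astype(_COLUMN_DTYPES)


def generate_exp1(params: GeneratorParams | None = None) -> pd.DataFrame:
    """Simulate the 2x2 complexity experiment (long format, one row per
    word).  Deterministic for fixed params and seed."""
    return _generate(params or GeneratorParams(), experiment=1)


def generate_exp2(params: GeneratorParams | None = None) -> pd.DataFrame:
    """Simulate the 2x2 colour-congruence experiment."""
    return _generate(params or GeneratorParams.exp2(), experiment=2)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------


def write_dataset(dataset: pd.DataFrame, path) -> None:
    """Write a dataset as CSV with the fixed documented header."""
    missing = [c for c in DATASET_COLUMNS if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset is missing columns: {missing}")
    dataset[DATASET_COLUMNS].to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read a dataset CSV, validating header and row shape.

    Malformed rows raise a parse error naming the offending line.
    """
    import warnings

    try:
        with warnings.catch_warnings():
            # rows with surplus fields only warn under index_col=False;
            # for a fixed-schema table they are malformed rows
            warnings.simplefilter("error", pd.errors.ParserWarning)
            raw = pd.read_csv(
                path, dtype=str, index_col=False, on_bad_lines="error"
            )
    except (pd.errors.ParserError, pd.errors.ParserWarning) as err:
        raise ValueError(f"malformed dataset CSV: {err}") from err
    missing = [c for c in DATASET_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"dataset CSV is missing columns: {missing}")
    if list(raw.columns) != DATASET_COLUMNS:
        raise ValueError(
            f"malformed dataset CSV: unexpected columns {list(raw.columns)}"
        )
    df = pd.DataFrame(index=raw.index)
    for col, dtype in _COLUMN_DTYPES.items():
        try:
            if dtype == "bool":
                vals = raw[col].map({"True": True, "False": False})
                if vals.isna().any():
                    bad = int(vals.index[vals.isna()][0]) + 2  # header + 1-based
                    raise ValueError(f"non-boolean {col!r} at line {bad}")
                df[col] = vals.astype(bool)
            else:
                df[col] = raw[col].astype(dtype)
        except (ValueError, TypeError) as err:
            if "at line" in str(err):
                raise
            bad_mask = pd.to_numeric(raw[col], errors="coerce").isna()
            lineno = int(bad_mask.idxmax()) + 2 if bad_mask.any() else "?"
            raise ValueError(
                f"malformed value in column {col!r} at line {lineno}: {err}"
            ) from err
    if (df["rt_ms"] <= 0).any():
        bad = int(df.index[df["rt_ms"] <= 0][0]) + 2
        raise ValueError(f"non-positive RT at line {bad}")
    return df
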