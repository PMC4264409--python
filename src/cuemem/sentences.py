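"""Encoding interference and retrieval predictions for noun phrases.

Maps noun-phrase descriptions onto feature vectors and derives, per
condition of a 2x2 complexity design, the probability of sampling the
target NP at the retrieval-triggering verb.

The mapping: every NP carries a small set of *form* tokens (syntactic
frame features, identical across NPs), one head-noun token unique to the
NP, and one unique semantic token per prenominal modifier.  Elaborating an
NP therefore adds contextually unique features without touching what it
shares with its neighbours.

Encoding interference is modelled as feature overwriting: when two NPs
match in form (same modifier count, hence the same syntactic frame), each
form feature they share is lost, in each member of the pair independently,
with a configurable probability.  At retrieval the probe specifies the
target's original encoding, while the target candidate is its current,
degraded trace — so encoding interference feeds into retrieval
interference: every overwritten feature makes the target resemble its own
retrieval cues less, lowering its sampling probability against intact-form
competitors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .features import (
    FeatureVector,
    RetrievalScenario,
    sampling_probabilities,
)

__all__ = [
    "NPSpec",
    "EncodingConfig",
    "InterferenceParams",
    "ConditionPrediction",
    "encode_np",
    "apply_encoding_interference",
    "exp1_design",
    "predict_conditions",
]

FORM_PREFIX = "F:"
LOST_PREFIX = "LOST:"

ROLES = ("NP1", "NP2_target", "NP3")


@dataclass(frozen=True)
class NPSpec:
    """One noun phrase: its role in the sentence and its elaboration.

    ``n_modifiers`` is 0 for a simple NP ("the general") and 2 for a
    complex one ("the victorious four-star general").
    """

    role: str
    n_modifiers: int = 0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.n_modifiers < 0:
            raise ValueError("n_modifiers must be >= 0")


@dataclass(frozen=True)
class EncodingConfig:
    """Feature-granularity knobs for the NP-to-vector mapping.

    base_form_features
        Number of shared syntactic/form tokens every NP carries (default 2).
    features_per_modifier
        Unique semantic tokens contributed by each modifier word (default 1).
    """

    base_form_features: int = 2
    features_per_modifier: int = 1

    def __post_init__(self) -> None:
        if self.base_form_features < 0 or self.features_per_modifier < 0:
            raise ValueError("feature counts must be >= 0")


@dataclass(frozen=True)
class InterferenceParams:
    """Feature-overwriting settings.

    overwrite_probability is the per-pair, per-shared-form-feature,
    per-member probability of loss; n_reps the Monte-Carlo replicate count
    used by :func:`predict_conditions`.
    """

    overwrite_probability: float = 0.3
    n_reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overwrite_probability <= 1.0:
            raise ValueError("overwrite_probability must lie in [0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass(frozen=True)
class ConditionPrediction:
    """Per-condition retrieval prediction with Monte-Carlo uncertainty."""

    condition: str
    target_probability: float
    mc_se: float
    intact_proportion: float


def encode_np(spec: NPSpec, config: EncodingConfig | None = None) -> FeatureVector:
    """Encode a noun phrase as a feature vector.

    Layout: shared form tokens first, then the unique head-noun token, then
    one unique semantic token per modifier.  Keeping form and head in fixed
    slots means two NPs always align positionally on what they share.
    """
    config = config or EncodingConfig()
    toks = [f"{FORM_PREFIX}{i}" for i in range(config.base_form_features)]
    toks.append(f"HEAD:{spec.role}")
    for m in range(spec.n_modifiers):
        for k in range(config.features_per_modifier):
            toks.append(f"SEM:{spec.role}:{m}.{k}")
    return FeatureVector(toks)


def _form_slots(trace: FeatureVector) -> list[int]:
    return [i for i, t in enumerate(trace.features) if t.startswith(FORM_PREFIX)]


def _match_in_form(a: FeatureVector, b: FeatureVector) -> bool:
    """Full form match: same length and identical tokens at every form slot.

    With the standard encoding this holds exactly when the two NPs have the
    same modifier count — the condition under which overwriting applies.
    """
    if len(a) != len(b):
        return False
    sa, sb = _form_slots(a), _form_slots(b)
    return sa == sb and all(a.features[i] == b.features[i] for i in sa)


def apply_encoding_interference(
    traces: Sequence[FeatureVector],
    params: InterferenceParams,
    rng: np.random.Generator | None = None,
) -> list[FeatureVector]:
    """Degrade traces by pairwise feature overwriting.

    For every pair of traces that match in form, each shared form feature is
    overwritten — replaced by an unmatchable lost token — in each member of
    the pair independently with ``params.overwrite_probability``.  Returns
    degraded copies; the inputs are untouched.  Deterministic for a fixed
    seed (or pass an explicit generator to share a stream).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    p = params.overwrite_probability
    lost: set[tuple[int, int]] = set()  # (trace index, slot)
    for i in range(len(traces)):
        for j in range(i + 1, len(traces)):
            if not _match_in_form(traces[i], traces[j]):
                continue
            for slot in _form_slots(traces[i]):
                if traces[i].features[slot] != traces[j].features[slot]:
                    continue
                if rng.random() < p:
                    lost.add((i, slot))
                if rng.random() < p:
                    lost.add((j, slot))
    out = []
    for i, trace in enumerate(traces):
        toks = list(trace.features)
        for slot in range(len(toks)):
            if (i, slot) in lost:
                toks[slot] = f"{LOST_PREFIX}{i}:{slot}"
        out.append(FeatureVector(toks))
    return out


def exp1_design(
    config: EncodingConfig | None = None,
) -> dict[str, tuple[NPSpec, NPSpec, NPSpec]]:
    """The 2x2 complexity design: NP1 and NP2 each simple (0 modifiers) or
    complex (2 modifiers); NP3 — the relative-clause subject — always simple.

    Condition labels read NP1-NP2, e.g. ``"complex-simple"`` = complex NP1,
    simple NP2.
    """
    del config  # feature granularity enters at encoding, not design, time
    out = {}
    for np1_label, np1_mods in (("simple", 0), ("complex", 2)):
        for np2_label, np2_mods in (("simple", 0), ("complex", 2)):
            out[f"{np1_label}-{np2_label}"] = (
                NPSpec("NP1", np1_mods),
                NPSpec("NP2_target", np2_mods),
                NPSpec("NP3", 0),
            )
    return out


def _target_probability(
    triple: tuple[NPSpec, NPSpec, NPSpec],
    config: EncodingConfig,
    params: InterferenceParams,
    rng: np.random.Generator,
    wildcard_policy: str,
) -> tuple[float, float]:
    """One interference replicate: sample overwriting, build the retrieval
    scenario, return (target probability, intact target proportion).

    The probe is the feature specification of the target's original
    encoding — the cues assembled at the retrieval site describe what was
    encoded, and the triggering verb adds no form cues of its own.  The
    *target candidate* is its current, possibly overwritten trace: slots
    whose binding was captured by a form-matched neighbour no longer
    support redintegration of the target.  Competitor candidates enter
    with their full form match to the probe: an overwritten shared
    feature is misbound, not erased — some form-matched trace still
    carries it — so losing it to a neighbour does not make a competitor
    less confusable with the probe's shared form cues.
    """
    traces = [encode_np(s, config) for s in triple]
    target_idx = next(i for i, s in enumerate(triple) if s.role == "NP2_target")
    degraded = apply_encoding_interference(traces, params, rng)
    candidates = list(traces)
    candidates[target_idx] = degraded[target_idx]
    scenario = RetrievalScenario(
        probe=traces[target_idx],
        traces=candidates,
        target_index=target_idx,
    )
    p_target = sampling_probabilities(scenario, wildcard_policy).target_probability
    n_lost = sum(
        1 for t in degraded[target_idx].features if t.startswith(LOST_PREFIX)
    )
    intact = 1.0 - n_lost / len(degraded[target_idx])
    return p_target, intact


def predict_conditions(
    design: dict[str, tuple[NPSpec, NPSpec, NPSpec]] | None = None,
    params: InterferenceParams | None = None,
    config: EncodingConfig | None = None,
    wildcard_policy: str = "mismatch",
) -> list[ConditionPrediction]:
    """Per-condition target sampling probability, averaged over
    interference replicates.

    With ``overwrite_probability = 0`` the model is deterministic and a
    single evaluation is reported with zero Monte-Carlo error.
    """
    design = design or exp1_design()
    params = params or InterferenceParams()
    config = config or EncodingConfig()
    rng = np.random.default_rng(params.seed)
    n_reps = 1 if params.overwrite_probability == 0.0 else params.n_reps
    out = []
    for condition, triple in design.items():
        probs = np.empty(n_reps)
        intacts = np.empty(n_reps)
        for r in range(n_reps):
            probs[r], intacts[r] = _target_probability(
                triple, config, params, rng, wildcard_policy
            )
        se = float(probs.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
        out.append(
            ConditionPrediction(
                condition=condition,
                target_probability=float(probs.mean()),
                mc_se=se,
                intact_proportion=float(intacts.mean()),
            )
        )
    return out
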