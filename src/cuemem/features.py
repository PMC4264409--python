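"""Feature-based cue redintegration: similarities and retrieval sampling.

Memory items are symbolic feature vectors (e.g. ``[C C 2 3 1]``).  A
retrieval probe — the lingering remnant of an encoding plus any contextual
cues — is compared slot by slot against every candidate trace.  The distance
``d`` between probe and candidate is the proportion of mismatching features
among the compared features, similarity is ``exp(-d)``, and the probability
of sampling a candidate is its similarity normalized over all candidates
(a Luce choice ratio).

Two asymmetries define the comparison:

* the *probe* fixes how many features are compared — probe slots with no
  counterpart in a candidate count as mismatches, while candidate features
  beyond the probe's length are ignored;
* a ``"?"`` slot marks a degraded (blurry) probe feature and, under the
  default policy, fails to match anything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "WILDCARD",
    "FeatureVector",
    "RetrievalScenario",
    "SamplingResult",
    "SweepSpec",
    "count_mismatches",
    "distance",
    "similarity",
    "sampling_probabilities",
    "printed_table",
    "build_sweep_scenario",
    "distinctiveness_sweep",
    "competitor_sweep",
    "read_scenarios",
    "load_reference_scenarios",
]

#: Token marking a degraded/blurry probe slot.
WILDCARD = "?"

#: Wildcard scoring policies: a blurry slot either fails to match anything
#: ("mismatch", the default) or is dropped from the compared features
#: ("exclude"), which also shrinks the denominator.
WILDCARD_POLICIES = ("mismatch", "exclude")


@dataclass(frozen=True)
class FeatureVector:
    """An ordered sequence of symbolic feature tokens.

    Stored memory traces must consist of concrete tokens; only retrieval
    probes may carry the ``"?"`` wildcard marking a degraded slot.
    """

    features: tuple[str, ...]

    def __init__(self, features: Iterable[str]) -> None:
        toks = tuple(str(t) for t in features)
        if len(toks) < 1:
            raise ValueError("a feature vector needs at least one feature")
        if any(not t for t in toks):
            raise ValueError("feature tokens must be non-empty strings")
        object.__setattr__(self, "features", toks)

    @classmethod
    def from_string(cls, text: str) -> "FeatureVector":
        """Parse a whitespace-separated token list, e.g. ``"C C 2 3 1"``."""
        return cls(text.split())

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[str]:
        return iter(self.features)

    def __str__(self) -> str:
        return "[" + " ".join(self.features) + "]"

    @property
    def has_wildcard(self) -> bool:
        return WILDCARD in self.features


def _check_trace(trace: FeatureVector, what: str = "trace") -> None:
    if trace.has_wildcard:
        raise ValueError(
            f"{what} {trace} contains the wildcard {WILDCARD!r}; "
            "degraded slots are only meaningful in probes"
        )


@dataclass(frozen=True)
class RetrievalScenario:
    """One retrieval probe compared against a set of candidate traces."""

    probe: FeatureVector
    traces: tuple[FeatureVector, ...]
    target_index: int

    def __init__(
        self,
        probe: FeatureVector,
        traces: Sequence[FeatureVector],
        target_index: int,
    ) -> None:
        traces = tuple(traces)
        if not traces:
            raise ValueError("a retrieval scenario needs at least one trace")
        for t in traces:
            _check_trace(t)
        if not 0 <= target_index < len(traces):
            raise ValueError(
                f"target_index {target_index} out of range for {len(traces)} traces"
            )
        object.__setattr__(self, "probe", probe)
        object.__setattr__(self, "traces", traces)
        object.__setattr__(self, "target_index", target_index)

    @property
    def target(self) -> FeatureVector:
        return self.traces[self.target_index]


@dataclass(frozen=True)
class SamplingResult:
    """Similarities and normalized sampling probabilities for one scenario."""

    similarities: tuple[float, ...]
    probabilities: tuple[float, ...]
    target_index: int

    @property
    def target_probability(self) -> float:
        return self.probabilities[self.target_index]


def _validate_policy(wildcard_policy: str) -> None:
    if wildcard_policy not in WILDCARD_POLICIES:
        raise ValueError(
            f"unknown wildcard policy {wildcard_policy!r}; "
            f"expected one of {WILDCARD_POLICIES}"
        )


def count_mismatches(
    probe: FeatureVector,
    candidate: FeatureVector,
    wildcard_policy: str = "mismatch",
) -> int:
    """Number of probe slots that fail to match the candidate.

    Comparison runs over the *probe's* positions only: a probe slot with no
    candidate counterpart is a mismatch, candidate features beyond the
    probe's length are ignored.  A ``"?"`` slot counts as a mismatch under
    the default policy and is skipped entirely under ``"exclude"``.
    """
    _validate_policy(wildcard_policy)
    if len(probe) < 1:  # unreachable for a valid FeatureVector; belt and braces
        raise ValueError("probe must have at least one feature")
    n = 0
    for i, tok in enumerate(probe):
        if tok == WILDCARD:
            if wildcard_policy == "mismatch":
                n += 1
            continue
        if i >= len(candidate.features) or candidate.features[i] != tok:
            n += 1
    return n


def _n_compared(probe: FeatureVector, wildcard_policy: str) -> int:
    if wildcard_policy == "exclude":
        return sum(1 for t in probe if t != WILDCARD)
    return len(probe)


def distance(
    probe: FeatureVector,
    candidate: FeatureVector,
    wildcard_policy: str = "mismatch",
) -> float:
    """Mismatching features divided by the number of compared features.

    The denominator is the probe's feature count (minus excluded wildcard
    slots under the ``"exclude"`` policy), so ``d`` always lies in [0, 1].
    """
    _validate_policy(wildcard_policy)
    denom = _n_compared(probe, wildcard_policy)
    if denom == 0:
        raise ValueError(
            "no compared features: the probe consists entirely of excluded "
            "wildcard slots"
        )
    return count_mismatches(probe, candidate, wildcard_policy) / denom


def similarity(
    probe: FeatureVector,
    candidate: FeatureVector,
    wildcard_policy: str = "mismatch",
) -> float:
    """Similarity ``s = exp(-d)``; lies in [e^(-1), 1]."""
    return math.exp(-distance(probe, candidate, wildcard_policy))


def sampling_probabilities(
    scenario: RetrievalScenario,
    wildcard_policy: str = "mismatch",
) -> SamplingResult:
    """Luce-ratio sampling probabilities over a scenario's candidate traces.

    probability_i = s(probe, trace_i) / sum_j s(probe, trace_j)
    """
    sims = tuple(
        similarity(scenario.probe, t, wildcard_policy) for t in scenario.traces
    )
    total = sum(sims)
    probs = tuple(s / total for s in sims)
    return SamplingResult(sims, probs, scenario.target_index)


def printed_table(
    scenario: RetrievalScenario,
    precision: int = 2,
    wildcard_policy: str = "mismatch",
) -> pd.DataFrame:
    """Reproduce a scenario as a printed similarity/probability table.

    Published worked examples of this model report similarities rounded to a
    fixed precision and sampling probabilities normalized from those
    *rounded* similarities (the two are not interchangeable once rounded:
    with an eight-feature probe the exact target probability is 0.514 while
    the value normalized from 2-d.p. similarities prints as 0.52).  This
    helper reports both columns at the table's precision so printed tables
    can be checked cell for cell.  For any downstream computation use
    :func:`sampling_probabilities`, which is exact.
    """
    sims = [
        round(similarity(scenario.probe, t, wildcard_policy), precision)
        for t in scenario.traces
    ]
    total = sum(sims)
    return pd.DataFrame(
        {
            "trace": [str(t) for t in scenario.traces],
            "similarity": sims,
            "probability": [round(s / total, precision) for s in sims],
        }
    )


# ---------------------------------------------------------------------------
# Distinctiveness / competitor sweeps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepSpec:
    """Grid for the distinctiveness/competitor sweeps.

    m: probe features matching each competitor; u: features unique to the
    target; n: number of competitors.  Defaults cover the standard picture —
    the isolation advantage saturating in u, and retrieval probability
    collapsing in the number of competitors.
    """

    m_values: tuple[int, ...] = tuple(range(2, 11))
    u_values: tuple[int, ...] = tuple(range(0, 21))
    n_values: tuple[int, ...] = (2,)
    comparison_mode: str = "probe_denominator"

    def __post_init__(self) -> None:
        if self.comparison_mode != "probe_denominator":
            raise ValueError("only probe_denominator comparison is defined")
        for m in self.m_values:
            for u in self.u_values:
                if m + u < 1:
                    raise ValueError("every swept point needs m + u >= 1")


def build_sweep_scenario(m: int, u: int, n_competitors: int) -> RetrievalScenario:
    """Abstract scenario: an intact probe, one target, n identical-structure
    competitors.

    The probe equals the target trace: ``m`` features shared with every
    competitor plus ``u`` features unique to the target.  Each competitor
    matches the probe on exactly the ``m`` shared positions and mismatches
    on the ``u`` unique positions.
    """
    if m < 0 or u < 0 or m + u < 1 or n_competitors < 1:
        raise ValueError(
            "need m >= 0, u >= 0, m + u >= 1 and at least one competitor"
        )
    shared = [f"S{i}" for i in range(m)]
    target = FeatureVector(shared + [f"U{i}" for i in range(u)])
    competitors = [
        FeatureVector(shared + [f"D{j}.{i}" for i in range(u)])
        if u
        else FeatureVector(shared)
        for j in range(n_competitors)
    ]
    return RetrievalScenario(
        probe=target, traces=[target, *competitors], target_index=0
    )


def _sweep_point(m: int, u: int, n: int) -> float:
    return sampling_probabilities(build_sweep_scenario(m, u, n)).target_probability


def distinctiveness_sweep(spec: SweepSpec | None = None) -> pd.DataFrame:
    """Target sampling probability over a (m, u, n) grid.

    Each point is deterministic under the positional model, so the table
    holds exact values, no averaging.  Columns:
    ``m, u, n_competitors, target_probability``.
    """
    spec = spec or SweepSpec()
    rows = [
        (m, u, n, _sweep_point(m, u, n))
        for n in spec.n_values
        for m in spec.m_values
        for u in spec.u_values
    ]
    return pd.DataFrame(
        rows, columns=["m", "u", "n_competitors", "target_probability"]
    )


def competitor_sweep(
    m: int = 2,
    u_values: Iterable[int] = tuple(range(0, 21)),
    n_values: Iterable[int] = tuple(range(1, 11)),
) -> pd.DataFrame:
    """Same table as :func:`distinctiveness_sweep`, varying competitor count."""
    spec = SweepSpec(
        m_values=(m,), u_values=tuple(u_values), n_values=tuple(n_values)
    )
    return distinctiveness_sweep(spec)


# ---------------------------------------------------------------------------
# Scenario fixtures
# ---------------------------------------------------------------------------


def _parse_scenario_block(lines: list[tuple[int, str]]) -> RetrievalScenario:
    probe: FeatureVector | None = None
    traces: list[FeatureVector] = []
    target_index: int | None = None
    for lineno, line in lines:
        key, _, rest = line.partition(":")
        key = key.strip().lower()
        rest = rest.strip()
        if key == "probe":
            probe = FeatureVector.from_string(rest)
        elif key == "trace":
            if rest.startswith("*"):
                target_index = len(traces)
                rest = rest[1:].strip()
            traces.append(FeatureVector.from_string(rest))
        else:
            raise ValueError(f"line {lineno}: expected 'probe:' or 'trace:', got {line!r}")
    if probe is None:
        raise ValueError(f"scenario ending at line {lines[-1][0]} has no probe")
    if target_index is None:
        raise ValueError(
            f"scenario ending at line {lines[-1][0]} marks no target trace "
            "(prefix one trace with '*')"
        )
    return RetrievalScenario(probe, traces, target_index)


def read_scenarios(path_or_buffer) -> list[RetrievalScenario]:
    """Read retrieval scenarios from a small plain-text format.

    One scenario per blank-line-separated block::

        probe: C C 2 3 1
        trace: C C 1 2 3
        trace: * C C 2 3 1
        trace: C C 3 1 2

    Tokens are whitespace-separated; ``*`` marks the target trace; ``#``
    starts a comment line.
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer, encoding="utf-8") as fh:
            text = fh.read()
    scenarios: list[RetrievalScenario] = []
    block: list[tuple[int, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#"):
            continue
        if not line:
            if block:
                scenarios.append(_parse_scenario_block(block))
                block = []
            continue
        block.append((lineno, line))
    if block:
        scenarios.append(_parse_scenario_block(block))
    return scenarios


def load_reference_scenarios() -> list[RetrievalScenario]:
    """The two packaged worked retrieval contexts.

    An intact five-feature probe and the same probe elaborated with three
    features unique to the target, each against two permuted competitors —
    the minimal pair showing how contextually unique target features raise
    the target's sampling probability without touching probe–target
    similarity.
    """
    ref = resources.files("cuemem.data").joinpath("redintegration_scenarios.txt")
    with ref.open("r", encoding="utf-8") as fh:
        return read_scenarios(fh)
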