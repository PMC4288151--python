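"""Linking variant prevalence to coverage ratio, and the scenario test.

A mixed population of DNA molecules in which a fraction ``f`` carries a
tandem duplication of a segment shows mean relative coverage ``1 + f`` over
that segment (each carrier contributes two copies).  A deletion of the
complementary segment present in a fraction ``q`` of molecules depresses
its coverage to ``1 - q``, i.e. the undeleted segment appears enriched by
``1 / (1 - q)``.  Observed Rc values therefore invert exactly to a
prevalence under either scenario.

Whether an observed population-level Rc reflects a duplication or a
deletion is discriminated by how many of n sampled clones display the
coverage pattern: the count is Binomial(n, p) with p the scenario's
prevalence, and the ratio of the two binomial masses is the evidence for
one scenario over the other.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = [
    "ScenarioModel",
    "CloneSample",
    "expected_rc",
    "infer_prevalence",
    "clone_sampling_pmf",
    "scenario_likelihood_ratio",
]

SCENARIOS = ("duplication", "deletion")


@dataclass(frozen=True)
class ScenarioModel:
    """A structural-variant scenario with its population prevalence."""

    scenario: str
    prevalence: float

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")


@dataclass(frozen=True)
class CloneSample:
    """n clones sampled from a population, k of which display the pattern."""

    n_clones: int
    k_pattern: int

    def __post_init__(self) -> None:
        if not 0 <= self.k_pattern <= self.n_clones:
            raise ValueError("need 0 <= k <= n")


def expected_rc(model: ScenarioModel) -> float:
    """Forward model: Rc implied by a scenario and its prevalence."""
    if model.scenario == "duplication":
        return 1.0 + model.prevalence
    if model.prevalence >= 1.0:
        raise ValueError("deletion Rc is undefined at q = 1")
    return 1.0 / (1.0 - model.prevalence)


def infer_prevalence(rc: float, scenario: str, tol: float = 0.02) -> float:
    """Invert an observed Rc to a prevalence, clipped to [0, 1].

    Rc substantially below 1 (beyond ``tol``, which absorbs sampling noise
    on a variant-free genome) means the complementary segment is the
    amplified one; the caller should swap the segment orientation rather
    than have it silently reinterpreted here.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    if rc < 1.0 - tol:
        raise ValueError(
            "Rc < 1: the complementary segment is amplified; swap orientation"
        )
    if scenario == "duplication":
        return min(max(rc - 1.0, 0.0), 1.0)
    return min(max(1.0 - 1.0 / rc, 0.0), 1.0)


def clone_sampling_pmf(sample: CloneSample, prevalence: float) -> float:
    """Binomial(n, p) mass at k: chance that k of n clones show the pattern."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    return float(stats.binom.pmf(sample.k_pattern, sample.n_clones, prevalence))


def scenario_likelihood_ratio(
    sample: CloneSample, p_dup: float, p_del: float
) -> float:
    """Evidence for duplication over deletion from the clone sample.

    Ratio of the binomial masses of the observed clone count under the two
    scenario prevalences (e.g. those that each explain the population Rc).
    """
    num = clone_sampling_pmf(sample, p_dup)
    den = clone_sampling_pmf(sample, p_del)
    if den == 0.0:
        raise ZeroDivisionError("deletion-scenario pmf is zero")
    return num / den
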