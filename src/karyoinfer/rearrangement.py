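"""Homolog matching, fusion/fission inference and hybrid karyotype prediction.

Two related karyotypes with haploid numbers differing by one (here n = 5
and n = 6 in a parasitoid-wasp species complex) can be connected by a
single fusion or fission.  Because relative lengths (RL) are conserved
percentages of the haploid set, a fusion product must carry the summed RL
of its components; arm bookkeeping on the centromeric index (CI) then
discriminates the mechanism:

* centric fusion (after a pericentric inversion making the metacentric
  component near-acrocentric): product arms are the two component totals,
  so predicted CI = 100 · min(RL1, RL2) / (RL1 + RL2);
* tandem fusion of the acrocentric onto the long or the short arm of the
  metacentric component, which extends that arm by the acrocentric's RL.

Homologs shared by the two karyotypes are identified by a minimum-cost
one-to-one assignment on SD-standardised RL and CI differences; an F1
hybrid female is then predicted to carry one haploid set from each parent,
with matched chromosomes paired and the rest as single copies.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm

from .errors import ComputationError, ValidationError
from .morphometrics import ChromosomeProfile, KaryotypeProfile

logger = logging.getLogger(__name__)

#: Floor (percent) on pooled SDs in standardised distances; printed SDs of 0
#: (e.g. a CI fixed at 0 for an acrocentric) would otherwise blow up costs.
SD_FLOOR = 0.5

#: Default dissolution threshold on the standardised matching distance
#: (roughly a 3-sigma rule on each coordinate).
DEFAULT_THRESHOLD = 3.0

MECHANISMS = (
    "centric_fusion_with_pericentric_inversion",
    "tandem_fusion_onto_long_arm",
    "tandem_fusion_onto_short_arm",
)


@dataclass(frozen=True)
class HomologMatching:
    """One-to-one correspondence between chromosomes of two karyotypes."""

    karyotype_a: str
    karyotype_b: str
    pairs: tuple[tuple[str, str, float], ...]  # (label_a, label_b, distance)
    unmatched_a: tuple[str, ...]
    unmatched_b: tuple[str, ...]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "karyotype_a": self.karyotype_a,
            "karyotype_b": self.karyotype_b,
            "pairs": [list(p) for p in self.pairs],
            "unmatched_a": list(self.unmatched_a),
            "unmatched_b": list(self.unmatched_b),
            "threshold": self.threshold,
        }


@dataclass(frozen=True)
class MechanismScore:
    """Predicted product CI under one fusion mechanism and its deviation."""

    mechanism: str
    predicted_ci: float
    abs_deviation: float

    def to_dict(self) -> dict:
        return {"mechanism": self.mechanism, "predicted_ci": self.predicted_ci,
                "abs_deviation": self.abs_deviation}


@dataclass(frozen=True)
class RearrangementCandidate:
    """A (component, component) -> product sum-compatibility hypothesis."""

    event_type: str  # "fusion" | "fission"
    component_labels: tuple[str, str]
    product_label: str
    summed_rl: float
    product_rl: float
    z_statistic: float
    p_value: float
    mechanism_scores: tuple[MechanismScore, ...] = ()

    def to_dict(self) -> dict:
        return {
            "event_type": self.event_type,
            "component_labels": list(self.component_labels),
            "product_label": self.product_label,
            "summed_rl": self.summed_rl,
            "product_rl": self.product_rl,
            "z_statistic": self.z_statistic,
            "p_value": self.p_value,
            "mechanism_scores": [m.to_dict() for m in self.mechanism_scores],
        }


@dataclass(frozen=True)
class HybridKaryotype:
    """Predicted F1 chromosome complement: one haploid set from each parent."""

    karyotype_a: str
    karyotype_b: str
    chromosome_labels: tuple[str, ...]  # qualified as "<karyotype>:<label>"
    paired: tuple[tuple[str, str], ...]
    singletons_a: tuple[str, ...]
    singletons_b: tuple[str, ...]

    @property
    def total_count(self) -> int:
        return len(self.chromosome_labels)

    @property
    def singletons(self) -> tuple[str, ...]:
        return tuple(f"{self.karyotype_a}:{l}" for l in self.singletons_a) + tuple(
            f"{self.karyotype_b}:{l}" for l in self.singletons_b)

    def to_dict(self) -> dict:
        return {
            "karyotype_a": self.karyotype_a,
            "karyotype_b": self.karyotype_b,
            "total_count": self.total_count,
            "paired": [list(p) for p in self.paired],
            "singletons": list(self.singletons),
        }


# ---------------------------------------------------------------------------
# homolog matching
# ---------------------------------------------------------------------------


def _pooled_sd(sd1: float, sd2: float) -> float:
    return max(math.sqrt((sd1 * sd1 + sd2 * sd2) / 2.0), SD_FLOOR)


def matching_cost(ca: ChromosomeProfile, cb: ChromosomeProfile) -> float:
    """Standardised morphometric distance |ΔRL|/s_RL + |ΔCI|/s_CI."""
    s_rl = _pooled_sd(ca.rl_sd, cb.rl_sd)
    s_ci = _pooled_sd(ca.ci_sd, cb.ci_sd)
    return abs(ca.rl_mean - cb.rl_mean) / s_rl + abs(ca.ci_mean - cb.ci_mean) / s_ci


def match_homologs(a: KaryotypeProfile, b: KaryotypeProfile,
                   threshold: float = DEFAULT_THRESHOLD) -> HomologMatching:
    """Optimal one-to-one homolog assignment between two karyotypes.

    Minimises the total standardised distance over all one-to-one
    assignments (Hungarian algorithm; rectangular cost matrix when the
    haploid numbers differ), then dissolves any pair whose distance exceeds
    ``threshold`` into the unmatched sets.  Costs are capped just above the
    threshold before solving: a chromosome with no admissible partner then
    pays the same flat price wherever it lands and cannot distort the
    assignment of genuinely similar pairs.
    """
    if threshold <= 0:
        raise ValidationError("matching threshold must be positive")
    cost = np.array([[matching_cost(ca, cb) for cb in b.chromosomes]
                     for ca in a.chromosomes])
    capped = np.minimum(cost, threshold * (1.0 + 1e-9))
    rows, cols = linear_sum_assignment(capped)
    pairs = []
    matched_a, matched_b = set(), set()
    for i, j in zip(rows, cols):
        d = float(cost[i, j])
        la, lb = a.chromosomes[i].label, b.chromosomes[j].label
        if d <= threshold:
            pairs.append((la, lb, d))
            matched_a.add(la)
            matched_b.add(lb)
        else:
            logger.debug("dissolved pair (%s, %s): distance %.2f > %.2f",
                         la, lb, d, threshold)
    pairs.sort(key=lambda p: (p[0], p[1]))
    return HomologMatching(
        karyotype_a=a.karyotype_id,
        karyotype_b=b.karyotype_id,
        pairs=tuple(pairs),
        unmatched_a=tuple(l for l in a.labels if l not in matched_a),
        unmatched_b=tuple(l for l in b.labels if l not in matched_b),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# mechanism scoring
# ---------------------------------------------------------------------------


def _arms(c: ChromosomeProfile) -> tuple[float, float]:
    """Recover (short, long) arm RLs from mean RL and CI."""
    short = c.ci_mean * c.rl_mean / 100.0
    return short, c.rl_mean - short


def score_mechanisms(comp1: ChromosomeProfile, comp2: ChromosomeProfile,
                     product: ChromosomeProfile) -> tuple[MechanismScore, ...]:
    """Score fusion mechanisms by predicted product CI vs. observed CI.

    The component with the larger CI plays the metacentric role; the other
    (ideally acrocentric) is tandem-joined onto one of its arms, or both are
    joined at the centromere (centric fusion, which for a metacentric
    component presupposes a pericentric inversion first).  Scores are mean
    CIs only — no uncertainty propagation — ranked by absolute deviation.
    """
    meta, acro = (comp1, comp2) if comp1.ci_mean >= comp2.ci_mean else (comp2, comp1)
    total = comp1.rl_mean + comp2.rl_mean
    short_m, long_m = _arms(meta)

    def ci_of(arm1: float, arm2: float) -> float:
        return 100.0 * min(arm1, arm2) / (arm1 + arm2)

    predictions = {
        "centric_fusion_with_pericentric_inversion": ci_of(comp1.rl_mean, comp2.rl_mean),
        "tandem_fusion_onto_long_arm": ci_of(short_m, long_m + acro.rl_mean),
        "tandem_fusion_onto_short_arm": ci_of(short_m + acro.rl_mean, long_m),
    }
    # With a zero-length short arm (both components acrocentric) the two
    # tandem attachments collapse: joining onto the empty short arm is the
    # centric-fusion geometry.  Report a single tandem entry then.
    tshort = predictions["tandem_fusion_onto_short_arm"]
    if (math.isclose(tshort, predictions["tandem_fusion_onto_long_arm"], abs_tol=1e-12)
            or math.isclose(tshort,
                            predictions["centric_fusion_with_pericentric_inversion"],
                            abs_tol=1e-12)):
        logger.warning("tandem mechanisms degenerate for components with CI %.3g/%.3g; "
                       "reporting a single tandem entry", comp1.ci_mean, comp2.ci_mean)
        del predictions["tandem_fusion_onto_short_arm"]
    scores = [
        MechanismScore(mechanism=m, predicted_ci=ci,
                       abs_deviation=abs(ci - product.ci_mean))
        for m, ci in predictions.items()
    ]
    scores.sort(key=lambda s: (s.abs_deviation, s.mechanism))
    assert all(0.0 <= s.predicted_ci <= 50.0 for s in scores), "CI prediction out of range"
    return tuple(scores)


# ---------------------------------------------------------------------------
# fusion / fission detection
# ---------------------------------------------------------------------------


def _sum_test(product: ChromosomeProfile, c1: ChromosomeProfile,
              c2: ChromosomeProfile, n_prod: int, n_comp: int) -> tuple[float, float, float]:
    """z and two-sided p for RL(product) = RL(c1) + RL(c2).

    Marginal SDs only; within-plate RL covariances (compositionally
    negative) are unknown from published tables and ignored, which is
    conservative for the sum.
    """
    summed = c1.rl_mean + c2.rl_mean
    se = math.sqrt(product.rl_sd ** 2 / n_prod
                   + (c1.rl_sd ** 2 + c2.rl_sd ** 2) / n_comp)
    if se == 0:
        z = 0.0 if math.isclose(product.rl_mean, summed, abs_tol=1e-12) else math.inf
    else:
        z = (product.rl_mean - summed) / se
    p = 2.0 * float(norm.sf(abs(z))) if math.isfinite(z) else 0.0
    return summed, z, p


def _check_event_inputs(lower: KaryotypeProfile, higher: KaryotypeProfile) -> None:
    if lower.haploid_number == higher.haploid_number:
        raise ValidationError(
            "karyotypes have equal haploid numbers; fusion/fission direction is "
            "undefined — run homolog matching only")
    if lower.haploid_number > higher.haploid_number:
        raise ValidationError("first karyotype must have the lower haploid number")
    for k in (lower, higher):
        if any(c.n_metaphases < 2 for c in k.chromosomes):
            raise ComputationError(
                f"karyotype {k.karyotype_id} has chromosomes with N < 2; "
                "the RL-sum test needs sample SDs")


def detect_fusion_candidates(a: KaryotypeProfile, b: KaryotypeProfile,
                             matching: HomologMatching,
                             alpha: float = 0.05) -> list[RearrangementCandidate]:
    """Fusion hypotheses: which unmatched pair of ``b`` sums to an unmatched
    chromosome of ``a``?

    ``a`` is the lower-n (derived) karyotype, ``b`` the higher-n one.  A
    candidate is retained when RL-sum equality is NOT rejected (two-sided
    p ≥ alpha): the test screens out incompatible pairs, it does not prove
    identity.  Candidates are ranked by |z| ascending, ties by label order,
    and carry mechanism scores for the fusion routes.
    """
    _check_event_inputs(a, b)
    if {matching.karyotype_a, matching.karyotype_b} != {a.karyotype_id, b.karyotype_id}:
        raise ValidationError("matching does not relate these two karyotypes")
    flipped = matching.karyotype_a != a.karyotype_id
    unmatched_a = matching.unmatched_b if flipped else matching.unmatched_a
    unmatched_b = matching.unmatched_a if flipped else matching.unmatched_b

    candidates = []
    for prod_label in unmatched_a:
        prod = a.chromosome(prod_label)
        for l1, l2 in itertools.combinations(sorted(unmatched_b), 2):
            c1, c2 = b.chromosome(l1), b.chromosome(l2)
            summed, z, p = _sum_test(prod, c1, c2,
                                     prod.n_metaphases, c1.n_metaphases)
            if p >= alpha:
                candidates.append(RearrangementCandidate(
                    event_type="fusion",
                    component_labels=(l1, l2),
                    product_label=prod_label,
                    summed_rl=summed,
                    product_rl=prod.rl_mean,
                    z_statistic=z,
                    p_value=p,
                    mechanism_scores=score_mechanisms(c1, c2, prod),
                ))
    candidates.sort(key=lambda c: (abs(c.z_statistic), c.product_label,
                                   c.component_labels))
    return candidates


def detect_fission_candidates(a: KaryotypeProfile, b: KaryotypeProfile,
                              matching: HomologMatching,
                              alpha: float = 0.05) -> list[RearrangementCandidate]:
    """Fission hypotheses: which unmatched pair of the aberrant higher-n
    karyotype ``a`` reconstitutes an unmatched chromosome of the reference
    ``b``?  Mirror image of fusion detection; no mechanism scores."""
    _check_event_inputs(b, a)
    if {matching.karyotype_a, matching.karyotype_b} != {a.karyotype_id, b.karyotype_id}:
        raise ValidationError("matching does not relate these two karyotypes")
    flipped = matching.karyotype_a != a.karyotype_id
    unmatched_a = matching.unmatched_b if flipped else matching.unmatched_a
    unmatched_b = matching.unmatched_a if flipped else matching.unmatched_b

    candidates = []
    for prod_label in unmatched_b:
        prod = b.chromosome(prod_label)
        for l1, l2 in itertools.combinations(sorted(unmatched_a), 2):
            c1, c2 = a.chromosome(l1), a.chromosome(l2)
            summed, z, p = _sum_test(prod, c1, c2,
                                     prod.n_metaphases, c1.n_metaphases)
            if p >= alpha:
                candidates.append(RearrangementCandidate(
                    event_type="fission",
                    component_labels=(l1, l2),
                    product_label=prod_label,
                    summed_rl=summed,
                    product_rl=prod.rl_mean,
                    z_statistic=z,
                    p_value=p,
                ))
    candidates.sort(key=lambda c: (abs(c.z_statistic), c.product_label,
                                   c.component_labels))
    return candidates


# ---------------------------------------------------------------------------
# hybrids and segregation
# ---------------------------------------------------------------------------


def predict_hybrid(a: KaryotypeProfile, b: KaryotypeProfile,
                   matching: HomologMatching) -> HybridKaryotype:
    """Predicted F1 female karyotype: union of one haploid set per parent.

    Matched chromosomes appear as homologous pairs; unmatched ones as
    single copies.  Total count is always n_a + n_b.
    """
    if {matching.karyotype_a, matching.karyotype_b} != {a.karyotype_id, b.karyotype_id}:
        raise ValidationError("matching does not relate these two karyotypes")
    if matching.karyotype_a != a.karyotype_id:
        a, b = b, a
    labels = tuple(f"{a.karyotype_id}:{l}" for l in a.labels) + tuple(
        f"{b.karyotype_id}:{l}" for l in b.labels)
    hybrid = HybridKaryotype(
        karyotype_a=a.karyotype_id,
        karyotype_b=b.karyotype_id,
        chromosome_labels=labels,
        paired=tuple((pa, pb) for pa, pb, _ in matching.pairs),
        singletons_a=matching.unmatched_a,
        singletons_b=matching.unmatched_b,
    )
    assert hybrid.total_count == a.haploid_number + b.haploid_number
    return hybrid


def segregation_expectation(h: HybridKaryotype, n_offspring: int,
                            seed: int) -> dict:
    """Expected and simulated gamete classes of a fusion-heterozygous hybrid.

    Requires the hybrid to carry exactly one fused/unfused alternative:
    one singleton from one parent (the fusion product) and two from the
    other (its components).  Each haploid gamete then receives either the
    product or the two components with probability 1/2 (no recombination
    model), yielding haploid numbers n_low and n_high = n_low + 1 in a 1:1
    ratio.  Returns exact expectations alongside seeded simulated counts.
    """
    n_low = len(h.paired) + 1  # gametes carrying the fused product
    n_high = len(h.paired) + 2
    sing_a, sing_b = len(h.singletons_a), len(h.singletons_b)
    if {sing_a, sing_b} != {1, 2}:
        raise ComputationError(
            "hybrid does not carry a recognised fusion trio "
            f"(singletons {sing_a} + {sing_b}; need 1 product vs 2 components)")
    if n_offspring < 0:
        raise ValidationError("n_offspring must be non-negative")
    rng = np.random.default_rng(seed)
    carries_product = int(rng.binomial(n_offspring, 0.5)) if n_offspring else 0
    return {
        "n_offspring": n_offspring,
        "classes": {
            f"n={n_low}": {"expected": n_offspring / 2.0, "simulated": carries_product},
            f"n={n_high}": {"expected": n_offspring / 2.0,
                            "simulated": n_offspring - carries_product},
        },
    }
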