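"""Ground-truthed synthetic data: karyotypes, rearrangements, noisy
metaphase measurements and clade-structured coding sequences.

The raw observations behind published karyotype tables (per-cell arm
lengths) and behind clade divergence summaries (the exact alignment) are
rarely deposited.  This module generates such raw data with known truth so
every estimator in the package can be validated end to end:

* exact karyotypes whose RL/CI equal a published summary table;
* rearrangement events (centric/tandem fusion, pericentric inversion,
  fission) applied to exact karyotypes with chromatin length conserved;
* per-metaphase measurement noise, multiplicative on whole-chromosome
  length and on the arm partition (chromosome condensation varies per cell
  roughly multiplicatively), truncated at ±3 CV;
* clade-structured sequences evolved under Jukes–Cantor on a star-of-stars
  tree whose branch lengths are solved from target mean p-distances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .errors import ValidationError
from .morphometrics import (ArmMeasurement, KaryotypeProfile, MetaphasePlate)
from .seqdist import AlignedSequenceSet, INVERT_MITO_TABLE

#: Default seed for entry points; an arbitrary fixed constant (the
#: description year of the wasp species the demo karyotypes belong to).
DEFAULT_SEED = 1841

EVENT_TYPES = ("centric_fusion", "tandem_fusion_long", "tandem_fusion_short",
               "pericentric_inversion", "fission")

#: CI at or below which a chromosome counts as (near-)acrocentric for the
#: centric-fusion precondition — the acrocentric class band.
NEAR_ACRO_CI = 12.5

NUCS = np.frombuffer(b"ACGT", dtype="S1")

#: Codons that are not stops under the invertebrate mitochondrial code.
STOP_CODONS = tuple(INVERT_MITO_TABLE.stop_codons)  # ("TAA", "TAG")


# ---------------------------------------------------------------------------
# true karyotypes and events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrueChromosome:
    label: str
    short_arm: float
    long_arm: float

    def __post_init__(self) -> None:
        if self.short_arm < 0 or self.long_arm < 0:
            raise ValidationError(f"negative arm on {self.label}")
        if self.short_arm + self.long_arm <= 0:
            raise ValidationError(f"zero-length chromosome {self.label}")
        if self.short_arm == 0 and self.long_arm == 0:
            raise ValidationError(f"both arms zero on {self.label}")

    @property
    def total(self) -> float:
        return self.short_arm + self.long_arm

    @property
    def ci(self) -> float:
        return 100.0 * min(self.short_arm, self.long_arm) / self.total


@dataclass(frozen=True)
class TrueKaryotype:
    """Noise-free karyotype in abstract length units (simulation truth)."""

    karyotype_id: str
    chromosomes: tuple[TrueChromosome, ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValidationError("empty karyotype")
        labels = [c.label for c in self.chromosomes]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate chromosome labels")

    @property
    def total_length(self) -> float:
        return sum(c.total for c in self.chromosomes)

    def chromosome(self, label: str) -> TrueChromosome:
        for c in self.chromosomes:
            if c.label == label:
                return c
        raise ValidationError(f"no chromosome {label!r} in {self.karyotype_id}")

    def to_dict(self) -> dict:
        return {"karyotype_id": self.karyotype_id,
                "chromosomes": [[c.label, c.short_arm, c.long_arm]
                                for c in self.chromosomes]}


@dataclass(frozen=True)
class RearrangementEvent:
    """One structural rearrangement to apply to a TrueKaryotype.

    ``operands``: one label for inversion/fission, two for fusions (for
    tandem fusions the first operand is the recipient whose arm is
    extended, the second the donor).  ``breakpoints`` are the pericentric
    inversion's breakpoint fractions (of the short and long arm, measured
    from the centromere).  ``split_fraction``/``split_arm`` position a
    fission break at that fraction of the designated arm from the
    centromere.
    """

    event_type: str
    operands: tuple[str, ...]
    breakpoints: tuple[float, float] | None = None
    split_fraction: float | None = None
    split_arm: str = "long"

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type!r}")
        need = 1 if self.event_type in ("pericentric_inversion", "fission") else 2
        if len(self.operands) != need:
            raise ValidationError(
                f"{self.event_type} takes {need} operand(s), got {len(self.operands)}")
        if self.event_type == "pericentric_inversion":
            if self.breakpoints is None or not all(0 < f < 1 for f in self.breakpoints):
                raise ValidationError("inversion breakpoint fractions must be in (0, 1)")
        if self.event_type == "fission":
            if self.split_fraction is None or not (0 < self.split_fraction < 1):
                raise ValidationError("fission split fraction must be in (0, 1)")
            if self.split_arm not in ("short", "long"):
                raise ValidationError("split_arm must be 'short' or 'long'")

    def to_dict(self) -> dict:
        return {"event_type": self.event_type, "operands": list(self.operands),
                "breakpoints": list(self.breakpoints) if self.breakpoints else None,
                "split_fraction": self.split_fraction, "split_arm": self.split_arm}


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative measurement noise for metaphase plates.

    ``rl_cv`` scales whole-chromosome length noise, ``arm_cv`` the arm
    partition jitter; both are coefficients of variation of truncated
    (±3 CV) Gaussians.  Defaults are calibrated so that N = 20 summaries
    show RL SDs of the magnitude seen in published wasp karyotype tables
    (≈ 0.75–1.8 RL percent).
    """

    rl_cv: float = 0.05
    arm_cv: float = 0.05
    n_metaphases: int = 20
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.rl_cv < 0 or self.arm_cv < 0:
            raise ValidationError("CVs must be non-negative")
        if self.n_metaphases < 1:
            raise ValidationError("n_metaphases must be >= 1")


def make_karyotype_from_table(summary: KaryotypeProfile) -> TrueKaryotype:
    """Exact karyotype whose arms reproduce a summary table's means.

    Arms: short = CI·RL/100, long = RL − short, in units where the haploid
    set totals ~100 (exactly the summed RL means).
    """
    chroms = tuple(
        TrueChromosome(
            label=c.label,
            short_arm=c.ci_mean * c.rl_mean / 100.0,
            long_arm=c.rl_mean - c.ci_mean * c.rl_mean / 100.0,
        )
        for c in summary.chromosomes
    )
    return TrueKaryotype(karyotype_id=summary.karyotype_id, chromosomes=chroms)


def apply_event(k: TrueKaryotype, e: RearrangementEvent,
                new_id: str | None = None) -> TrueKaryotype:
    """Apply one rearrangement; total chromatin length is conserved exactly."""
    new_id = new_id or f"{k.karyotype_id}+{e.event_type}"
    chroms = list(k.chromosomes)
    labels = [c.label for c in chroms]
    for op in e.operands:
        if op not in labels:
            raise ValidationError(f"operand {op!r} not in karyotype {k.karyotype_id}")

    if e.event_type == "pericentric_inversion":
        c = k.chromosome(e.operands[0])
        f_short, f_long = e.breakpoints
        a = f_short * c.short_arm  # segment of the short arm, from the centromere
        b = f_long * c.long_arm
        new_short, new_long = sorted((c.short_arm - a + b, c.long_arm - b + a))
        out = [TrueChromosome(c.label, new_short, new_long) if x.label == c.label else x
               for x in chroms]

    elif e.event_type in ("centric_fusion", "tandem_fusion_long", "tandem_fusion_short"):
        c1, c2 = (k.chromosome(l) for l in e.operands)
        if e.event_type == "centric_fusion":
            for c in (c1, c2):
                if c.ci > NEAR_ACRO_CI:
                    raise ValidationError(
                        f"centric fusion requires (near-)acrocentric operands; "
                        f"{c.label} has CI {c.ci:.1f} — apply a pericentric "
                        f"inversion first")
            short, long_ = sorted((c1.total, c2.total))
        elif e.event_type == "tandem_fusion_long":
            short, long_ = sorted((c1.short_arm, c1.long_arm + c2.total))
        else:
            short, long_ = sorted((c1.short_arm + c2.total, c1.long_arm))
        fused = TrueChromosome(f"{c1.label}+{c2.label}", short, long_)
        out = [x for x in chroms if x.label not in e.operands]
        out.append(fused)

    else:  # fission
        c = k.chromosome(e.operands[0])
        arm_len = c.long_arm if e.split_arm == "long" else c.short_arm
        if arm_len <= 0:
            raise ValidationError(f"cannot split zero-length {e.split_arm} arm of {c.label}")
        x = e.split_fraction * arm_len  # kept by the centromeric fragment
        if e.split_arm == "long":
            centric = TrueChromosome(f"{c.label}a", *sorted((c.short_arm, x)))
        else:
            centric = TrueChromosome(f"{c.label}a", *sorted((x, c.long_arm)))
        # the acentric fragment survives with a terminal neocentromere
        acentric = TrueChromosome(f"{c.label}b", 0.0, arm_len - x)
        out = [x_ for x_ in chroms if x_.label != c.label] + [centric, acentric]

    result = TrueKaryotype(karyotype_id=new_id, chromosomes=tuple(out))
    assert math.isclose(result.total_length, k.total_length, rel_tol=1e-12), \
        "chromatin length not conserved"
    return result


def sample_plates(k: TrueKaryotype, noise: NoiseModel) -> list[MetaphasePlate]:
    """Simulated metaphase measurement tables for one karyotype.

    Each chromosome's total on each plate is truth × (1 + ε) with
    ε ~ N(0, rl_cv) truncated at ±3 CV; the arm split is jittered the same
    way and renormalised to the sampled total.  Labels carry over from the
    truth, so downstream summaries can be compared to it directly.
    """
    rng = np.random.default_rng(noise.seed)

    def trunc_normal(cv: float, size) -> np.ndarray:
        if cv == 0:
            return np.zeros(size)
        eps = rng.normal(0.0, cv, size=size)
        return np.clip(eps, -3 * cv, 3 * cv)

    plates = []
    n_chrom = len(k.chromosomes)
    for p in range(noise.n_metaphases):
        mid = f"m{p + 1:02d}"
        tot_eps = trunc_normal(noise.rl_cv, n_chrom)
        arm_eps = trunc_normal(noise.arm_cv, (n_chrom, 2))
        ms = []
        for i, c in enumerate(k.chromosomes):
            total = c.total * (1.0 + tot_eps[i])
            assert total > 0
            s = c.short_arm * (1.0 + arm_eps[i, 0])
            l = c.long_arm * (1.0 + arm_eps[i, 1])
            scale = total / (s + l)
            ms.append(ArmMeasurement(metaphase_id=mid, chromosome_label=c.label,
                                     short_arm=s * scale, long_arm=l * scale))
        plates.append(MetaphasePlate(metaphase_id=mid, measurements=tuple(ms)))
    return plates


# ---------------------------------------------------------------------------
# clade-structured sequences
# ---------------------------------------------------------------------------


def p_to_jc(p: float) -> float:
    """Jukes–Cantor branch length (expected substitutions/site) for a target
    expected p-distance."""
    if not (0.0 <= p < 0.75):
        raise ValidationError(f"divergence target {p} infeasible under JC (needs < 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_to_p(d: float) -> float:
    """Expected p-distance between two sequences separated by JC distance d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _evolve(parent: np.ndarray, d: float, rng: np.random.Generator,
            coding: bool) -> np.ndarray:
    """One JC branch: per-site transition sampled from the exact JC kernel.

    In coding mode any codon that the branch turns into a stop (frame 0)
    is reverted to its parent codon, keeping the open reading frame intact;
    the realised divergence is thereby biased low by ≲ 2/64 of the change,
    which the calibration tolerances absorb.
    """
    p_change = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    child = parent.copy()
    hit = rng.random(parent.size) < p_change
    idx = np.flatnonzero(hit)
    if idx.size:
        cur = child[idx]
        # draw uniformly among the three other nucleotides
        offs = rng.integers(1, 4, size=idx.size)
        cur_codes = np.searchsorted(NUCS, cur)  # NUCS sorted: A C G T
        child[idx] = NUCS[(cur_codes + offs) % 4]
    if coding:
        codons = child.reshape(-1, 3)
        parent_codons = parent.reshape(-1, 3)
        joined = codons.view(dtype="S3").ravel()
        bad = np.isin(joined, np.array(STOP_CODONS, dtype="S3"))
        if bad.any():
            codons[bad] = parent_codons[bad]
    return child


def _solve_root_branches(clades: list[str], d_between: dict, tau: dict) -> dict:
    """Root→clade-ancestor branch lengths from ancestor–ancestor distances.

    Least-squares solve of b_i + b_j ≈ d'_ij with non-negativity (scipy
    NNLS); exact for three clades with additive targets.
    """
    if len(clades) == 1:
        return {clades[0]: 0.0}
    pairs = list(itertools.combinations(clades, 2))
    A = np.zeros((len(pairs), len(clades)))
    y = np.zeros(len(pairs))
    for r, (c1, c2) in enumerate(pairs):
        A[r, clades.index(c1)] = 1.0
        A[r, clades.index(c2)] = 1.0
        y[r] = max(d_between[frozenset((c1, c2))] - tau[c1] - tau[c2], 0.0)
    if len(clades) == 2:
        b = y[0] / 2.0
        return {c: b for c in clades}
    sol, _ = nnls(A, y)
    return dict(zip(clades, sol))


def simulate_clades(
    clade_sizes: dict[str, int],
    between_targets: dict[frozenset, float],
    within_targets: dict[str, float],
    length: int,
    *,
    coding: bool = False,
    seed: int = DEFAULT_SEED,
) -> tuple[AlignedSequenceSet, dict[str, str]]:
    """Clade-structured sequences with calibrated mean p-distances.

    A root sequence (codon-wise stop-free when ``coding``) evolves to one
    ancestor per clade and on to the tips under Jukes–Cantor.  Targets are
    expected mean p-distances; they are converted to additive JC branch
    lengths (``p_to_jc``), tip branches are half the within-clade target
    and root branches solve the between-clade system.  Returns the
    sequence set and an id→clade map.
    """
    if not clade_sizes:
        raise ValidationError("no clades requested")
    if length < 1 or (coding and length % 3):
        raise ValidationError("length must be positive (and divisible by 3 when coding)")
    clades = sorted(clade_sizes)
    for c, size in clade_sizes.items():
        if size < 1:
            raise ValidationError(f"clade {c} must have at least one sequence")
    for pair in itertools.combinations(clades, 2):
        if frozenset(pair) not in between_targets:
            raise ValidationError(f"missing between-clade target for {sorted(pair)}")

    tau = {c: p_to_jc(within_targets.get(c, 0.0)) / 2.0 for c in clades}
    d_between = {k: p_to_jc(v) for k, v in between_targets.items()}
    root_branches = _solve_root_branches(clades, d_between, tau)

    rng = np.random.default_rng(seed)
    if coding:
        ok = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
              if c not in STOP_CODONS]
        root = np.frombuffer(
            "".join(rng.choice(ok, size=length // 3)).encode(), dtype="S1").copy()
    else:
        root = rng.choice(NUCS, size=length)

    ids, seqs, clade_map = [], [], {}
    for c in clades:
        ancestor = _evolve(root, root_branches[c], rng, coding)
        for i in range(clade_sizes[c]):
            tip = _evolve(ancestor, tau[c], rng, coding)
            sid = f"{c}_{i + 1}"
            ids.append(sid)
            seqs.append(tip.tobytes().decode())
            clade_map[sid] = c
    return AlignedSequenceSet(ids=tuple(ids), sequences=tuple(seqs)), clade_map
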