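"""Karyotype morphometrics from metaphase arm-length measurements.

Chromosome size and shape in non-banded karyotypes are summarised by two
ratios measured on metaphase plates:

* relative length, ``RL = 100 * chromosome length / total length of the
  haploid set`` (sums to 100 within a plate), and
* centromeric index, ``CI = 100 * shorter arm / chromosome length``
  (50 = perfectly metacentric, 0 = telocentric/acrocentric).

Both are unit-free, so measurements may be in micrometres or pixels.
Per-karyotype summaries (mean ± SD over N metaphases, conventionally
N = 20) are the standard published form, alongside a centromere-position
class derived from CI following Levan-style arm-ratio guidelines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: CI breakpoints between acrocentric / subtelocentric / submetacentric /
#: metacentric, i.e. the arm-ratio guideline categories translated to CI.
CI_BREAKPOINTS = (12.5, 25.0, 37.5)

FOUR_CLASSES = ("acrocentric", "subtelocentric", "submetacentric", "metacentric")

#: Ordering used for monotonicity: class rank never decreases with CI.
CLASS_RANK = {name: i for i, name in enumerate(FOUR_CLASSES)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArmMeasurement:
    """Arm lengths of one chromosome on one metaphase plate.

    ``short_arm <= long_arm`` is enforced on construction by swapping (with a
    warning) — hand-built tables frequently list arms in the wrong order.
    """

    metaphase_id: str
    chromosome_label: str
    short_arm: float
    long_arm: float

    def __post_init__(self) -> None:
        if self.short_arm < 0 or self.long_arm < 0:
            raise ValidationError(
                f"negative arm length for {self.metaphase_id}/{self.chromosome_label}"
            )
        if self.short_arm + self.long_arm <= 0:
            raise ValidationError(
                f"zero-length chromosome {self.metaphase_id}/{self.chromosome_label}"
            )
        if self.short_arm > self.long_arm:
            logger.warning(
                "arm order swapped for %s/%s (short %.4g > long %.4g)",
                self.metaphase_id, self.chromosome_label, self.short_arm, self.long_arm,
            )
            s, l = self.long_arm, self.short_arm
            object.__setattr__(self, "short_arm", s)
            object.__setattr__(self, "long_arm", l)

    @property
    def total(self) -> float:
        return self.short_arm + self.long_arm


@dataclass(frozen=True)
class MetaphasePlate:
    """All chromosome measurements of one dividing cell."""

    metaphase_id: str
    measurements: tuple[ArmMeasurement, ...]
    ploidy_context: str = "haploid"

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValidationError(f"metaphase {self.metaphase_id} has no measurements")
        if self.ploidy_context not in ("haploid", "diploid"):
            raise ValidationError(f"unknown ploidy_context {self.ploidy_context!r}")
        for m in self.measurements:
            if m.metaphase_id != self.metaphase_id:
                raise ValidationError(
                    f"measurement {m.chromosome_label} carries metaphase_id "
                    f"{m.metaphase_id!r}, expected {self.metaphase_id!r}"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(m.chromosome_label for m in self.measurements)


@dataclass(frozen=True)
class ChromosomeProfile:
    """Mean ± SD morphometrics of one chromosome over N metaphases."""

    label: str
    rl_mean: float
    rl_sd: float
    ci_mean: float
    ci_sd: float
    n_metaphases: int
    centromere_class: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_mean <= 50.0):
            raise ValidationError(f"ci_mean {self.ci_mean} outside [0, 50] ({self.label})")
        if self.rl_mean <= 0:
            raise ValidationError(f"rl_mean must be positive ({self.label})")
        if self.rl_sd < 0 or self.ci_sd < 0:
            raise ValidationError(f"negative SD ({self.label})")
        if self.n_metaphases < 1:
            raise ValidationError(f"n_metaphases must be >= 1 ({self.label})")


@dataclass(frozen=True)
class KaryotypeProfile:
    """Ordered chromosome summaries of one haploid karyotype."""

    karyotype_id: str
    chromosomes: tuple[ChromosomeProfile, ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValidationError(f"karyotype {self.karyotype_id} is empty")
        labels = [c.label for c in self.chromosomes]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate chromosome labels in {self.karyotype_id}")
        total = sum(c.rl_mean for c in self.chromosomes)
        if abs(total - 100.0) > 0.5:
            raise ValidationError(
                f"RL means of {self.karyotype_id} sum to {total:.2f}, expected 100 ± 0.5"
            )

    @property
    def haploid_number(self) -> int:
        return len(self.chromosomes)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.chromosomes)

    def chromosome(self, label: str) -> ChromosomeProfile:
        for c in self.chromosomes:
            if c.label == label:
                return c
        raise ValidationError(f"no chromosome {label!r} in karyotype {self.karyotype_id}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def compute_rl(plate: MetaphasePlate) -> dict[str, float]:
    """Relative length (percent of the set total) per chromosome of a plate."""
    totals = np.array([m.total for m in plate.measurements], dtype=float)
    grand = totals.sum()
    if grand <= 0:
        raise ValidationError(f"plate {plate.metaphase_id} has zero total length")
    rl = 100.0 * totals / grand
    return dict(zip(plate.labels, rl))


def compute_ci(m: ArmMeasurement) -> float:
    """Centromeric index: 100 × shorter arm / chromosome length, in [0, 50]."""
    if m.total <= 0:
        raise ValidationError("zero-length chromosome has no centromeric index")
    return 100.0 * m.short_arm / m.total


def classify_centromere(ci: float, *, merge_submetacentric: bool = False) -> str:
    """Centromere-position class from CI.

    Half-open bands, lower-closed: acrocentric [0, 12.5), subtelocentric
    [12.5, 25), submetacentric [25, 37.5), metacentric [37.5, 50].  With
    ``merge_submetacentric`` the submetacentric band reports as metacentric,
    matching the three-class vocabulary of classic karyotype tables.
    """
    if not (0.0 <= ci <= 50.0) or math.isnan(ci):
        raise ValidationError(f"CI {ci} outside [0, 50]")
    idx = sum(ci >= b for b in CI_BREAKPOINTS)
    cls = FOUR_CLASSES[idx]
    if merge_submetacentric and cls == "submetacentric":
        cls = "metacentric"
    return cls


def _rank_labels(plate: MetaphasePlate) -> MetaphasePlate:
    """Assign labels 1..n by decreasing total length (largest = 1)."""
    order = sorted(range(len(plate.measurements)),
                   key=lambda i: -plate.measurements[i].total)
    relabelled = list(plate.measurements)
    for rank, i in enumerate(order, start=1):
        relabelled[i] = replace(plate.measurements[i], chromosome_label=str(rank))
    return replace(plate, measurements=tuple(relabelled))


def summarize_karyotype(
    plates: Sequence[MetaphasePlate],
    karyotype_id: str,
    *,
    merge_submetacentric: bool = False,
) -> KaryotypeProfile:
    """Mean ± SD of RL and CI per chromosome over a set of metaphase plates.

    Plates whose measurements carry no labels are labelled by rank of total
    length within each plate (largest = 1) — the only information-preserving
    default without banding.  Sample SD uses the N−1 denominator (0 for
    N = 1).  Chromosomes are ordered by decreasing mean RL in the result.
    """
    if not plates:
        raise ValidationError("no metaphase plates supplied")
    counts = {p.metaphase_id: len(p.measurements) for p in plates}
    if len(set(counts.values())) != 1:
        bad = {k: v for k, v in counts.items()}
        raise ValidationError(f"inconsistent chromosome counts across plates: {bad}")

    labelled = [
        p if all(m.chromosome_label for m in p.measurements) else _rank_labels(p)
        for p in plates
    ]
    label_sets = {frozenset(p.labels) for p in labelled}
    if len(label_sets) != 1:
        raise ValidationError(
            f"inconsistent chromosome labels across plates: {sorted(label_sets, key=sorted)}"
        )

    rl_rows: dict[str, list[float]] = {}
    ci_rows: dict[str, list[float]] = {}
    for p in labelled:
        rls = compute_rl(p)
        for m in p.measurements:
            rl_rows.setdefault(m.chromosome_label, []).append(rls[m.chromosome_label])
            ci_rows.setdefault(m.chromosome_label, []).append(compute_ci(m))

    n = len(plates)
    chroms = []
    for label in rl_rows:
        rl = np.asarray(rl_rows[label])
        ci = np.asarray(ci_rows[label])
        rl_sd = float(rl.std(ddof=1)) if n > 1 else 0.0
        ci_sd = float(ci.std(ddof=1)) if n > 1 else 0.0
        ci_mean = float(ci.mean())
        chroms.append(ChromosomeProfile(
            label=label,
            rl_mean=float(rl.mean()),
            rl_sd=rl_sd,
            ci_mean=ci_mean,
            ci_sd=ci_sd,
            n_metaphases=n,
            centromere_class=classify_centromere(
                ci_mean, merge_submetacentric=merge_submetacentric),
        ))
    chroms.sort(key=lambda c: (-c.rl_mean, -c.ci_mean, c.label))
    return KaryotypeProfile(karyotype_id=karyotype_id, chromosomes=tuple(chroms))


def order_karyogram(profile: KaryotypeProfile, matching=None) -> list[str]:
    """Karyogram label order: decreasing size, ties by decreasing CI (stable).

    With a homolog matching, karyotype-specific (unmatched) chromosomes come
    first and shared (matched) ones second, each group internally by
    decreasing mean RL — the layout used when two related karyotypes are
    printed side by side.
    """
    idx = {c.label: i for i, c in enumerate(profile.chromosomes)}

    def key(label: str):
        c = profile.chromosome(label)
        return (-c.rl_mean, -c.ci_mean, idx[label])

    if matching is None:
        return sorted(profile.labels, key=key)

    if matching.karyotype_a == profile.karyotype_id:
        matched = {pa for pa, _, _ in matching.pairs}
        unmatched = set(matching.unmatched_a)
    elif matching.karyotype_b == profile.karyotype_id:
        matched = {pb for _, pb, _ in matching.pairs}
        unmatched = set(matching.unmatched_b)
    else:
        raise ValidationError(
            f"matching relates {matching.karyotype_a!r}/{matching.karyotype_b!r}, "
            f"not {profile.karyotype_id!r}")
    known = matched | unmatched
    if known != set(profile.labels):
        raise ValidationError(
            f"matching labels {sorted(known)} do not cover karyotype "
            f"{profile.karyotype_id} labels {sorted(profile.labels)}")
    specific = sorted(unmatched, key=key)
    shared = sorted(matched, key=key)
    return specific + shared


# ---------------------------------------------------------------------------
# file dialects
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = ["metaphase_id", "chromosome_label", "short_arm", "long_arm"]
SUMMARY_COLUMNS = ["karyotype_id", "label", "rl_mean", "rl_sd",
                   "ci_mean", "ci_sd", "n_metaphases", "class"]


def read_measurements(path: str | Path, ploidy_context: str = "haploid") -> list[MetaphasePlate]:
    """Read a measurement TSV (one row per chromosome per metaphase).

    Columns: ``metaphase_id  chromosome_label  short_arm  long_arm``;
    ``#`` comments; empty chromosome_label triggers rank labelling later.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={
        "metaphase_id": str, "chromosome_label": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    plates = []
    for mid, grp in df.groupby("metaphase_id", sort=False):
        ms = tuple(
            ArmMeasurement(
                metaphase_id=str(mid),
                chromosome_label="" if pd.isna(row.chromosome_label) else str(row.chromosome_label),
                short_arm=float(row.short_arm),
                long_arm=float(row.long_arm),
            )
            for row in grp.itertuples()
        )
        plates.append(MetaphasePlate(metaphase_id=str(mid), measurements=ms,
                                     ploidy_context=ploidy_context))
    if not plates:
        raise ValidationError(f"{path}: no measurements")
    return plates


def write_measurements(plates: Iterable[MetaphasePlate], path: str | Path) -> None:
    rows = [
        (m.metaphase_id, m.chromosome_label, m.short_arm, m.long_arm)
        for p in plates for m in p.measurements
    ]
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_karyotype_summaries(path: str | Path) -> dict[str, KaryotypeProfile]:
    """Read a karyotype summary TSV; returns profiles keyed by karyotype_id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"karyotype_id": str, "label": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    out = {}
    for kid, grp in df.groupby("karyotype_id", sort=False):
        chroms = tuple(
            ChromosomeProfile(
                label=str(r["label"]), rl_mean=float(r["rl_mean"]), rl_sd=float(r["rl_sd"]),
                ci_mean=float(r["ci_mean"]), ci_sd=float(r["ci_sd"]),
                n_metaphases=int(r["n_metaphases"]), centromere_class=str(r["class"]),
            )
            for _, r in grp.iterrows()
        )
        out[str(kid)] = KaryotypeProfile(karyotype_id=str(kid), chromosomes=chroms)
    return out


def write_karyotype_summaries(profiles: Iterable[KaryotypeProfile], path: str | Path,
                              *, decimals: int | None = 2) -> None:
    """Write profiles as a summary TSV (two decimals by default, table style)."""
    rows = []
    for p in profiles:
        for c in p.chromosomes:
            rows.append((p.karyotype_id, c.label, c.rl_mean, c.rl_sd,
                         c.ci_mean, c.ci_sd, c.n_metaphases, c.centromere_class))
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if decimals is not None:
        for col in ("rl_mean", "rl_sd", "ci_mean", "ci_sd"):
            df[col] = df[col].round(decimals)
    df.to_csv(path, sep="\t", index=False)
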