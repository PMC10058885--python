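"""CRED-RA methylation typing from HpaII/MspI lane triplets.

HpaII and MspI are isoschizomers of the CCGG site with complementary
methylation sensitivities.  For each band, three lanes are scored: the
undigested template (x), the HpaII-digested template (y) and the
MspI-digested template (z).  A band survives a digestion lane only if the
enzyme was blocked inside its amplicon, so the (y, z) presence pair reads
out the methylation state of the site:

    ========  =========  =========  ==================
    type      HpaII      MspI       pattern
    ========  =========  =========  ==================
    I         cuts       cuts       non-methylation
    II        cuts       blocked    semi-methylation
    III       blocked    cuts       full-methylation
    IV        blocked    blocked    full-methylation
    ========  =========  =========  ==================

so on presence bits with x=1: (y, z) = (0,0) -> I, (0,1) -> II,
(1,0) -> III, (1,1) -> IV.  A band absent from the undigested lane (x=0)
never amplified and carries no methylation information; it is tallied as
*unclassifiable* and excluded from all percentage denominators.

Pattern ratios over the four type counts:

    total % = (II + III + IV) / (I + II + III + IV) * 100
    full  % = (III + IV)      / (I + II + III + IV) * 100
    semi  % = II              / (I + II + III + IV) * 100

Two pathways compute them: from integer counts (the pipeline's path) and
from an already-published vector of type percentages, where the denominator
is taken as 100 and the ratios are the plain linear sums.  The two agree
whenever the percentage vector sums to 100.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .profiles_io import BandMatrix

__all__ = [
    "MethylationType",
    "LaneTriplet",
    "TypeCounts",
    "PatternRatios",
    "UNCLASSIFIABLE",
    "PATTERN_LABELS",
    "classify_band",
    "type_counts",
    "type_percentages",
    "pattern_ratios_from_counts",
    "pattern_ratios_from_percent_vector",
    "methylation_table",
]


class MethylationType(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"

    @property
    def pattern_label(self) -> str:
        return PATTERN_LABELS[self]


PATTERN_LABELS: Mapping[MethylationType, str] = {
    MethylationType.I: "non-methylation",
    MethylationType.II: "semi-methylation",
    MethylationType.III: "full-methylation",
    MethylationType.IV: "full-methylation",
}

UNCLASSIFIABLE = "unclassifiable"

_TYPE_BY_YZ = {
    (0, 0): MethylationType.I,
    (0, 1): MethylationType.II,
    (1, 0): MethylationType.III,
    (1, 1): MethylationType.IV,
}


@dataclass(frozen=True)
class LaneTriplet:
    """Presence bits for one band in the (X, HpaII, MspI) lanes."""

    x_present: int
    y_present: int
    z_present: int

    def __post_init__(self) -> None:
        for name in ("x_present", "y_present", "z_present"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")


def classify_band(t: LaneTriplet) -> MethylationType | None:
    """Map a lane triplet to a methylation type, or None (unclassifiable).

    Requires the band to amplify from the undigested template (x=1);
    otherwise returns None regardless of the digestion lanes.
    """
    if t.x_present == 0:
        return None
    return _TYPE_BY_YZ[(t.y_present, t.z_present)]


@dataclass(frozen=True)
class TypeCounts:
    """Per-sample tallies of methylation types plus unclassifiable bands."""

    sample_id: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        expected = {t.value for t in MethylationType} | {UNCLASSIFIABLE}
        if set(self.counts) != expected:
            raise ValueError(f"counts must have keys {sorted(expected)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def n_classifiable(self) -> int:
        return sum(self.counts[t.value] for t in MethylationType)

    @property
    def n_total(self) -> int:
        return self.n_classifiable + self.counts[UNCLASSIFIABLE]


@dataclass(frozen=True)
class PatternRatios:
    total_methylation_percent: float
    full_methylation_percent: float
    semi_methylation_percent: float
    non_methylation_percent: float


def type_counts(
    matrix: BandMatrix, sample_id: str, primer: str | None = None
) -> TypeCounts:
    """Classify every band triplet of one sample and tally the types.

    ``primer`` restricts the tally to one primer's bands (used by the
    per-primer averaging mode); default is all bands.
    """
    if matrix.assay != "CREDRA":
        raise ValueError("methylation typing needs a CRED-RA matrix (X/H/M lanes)")
    matrix.sample(sample_id)  # raises KeyError for unknown ids
    bands = matrix.bands if primer is None else matrix.bands_for_primer(primer)
    keys = [b.key for b in bands]
    x = matrix.presence.loc[keys, (sample_id, "X")].to_numpy()
    y = matrix.presence.loc[keys, (sample_id, "H")].to_numpy()
    z = matrix.presence.loc[keys, (sample_id, "M")].to_numpy()
    counts = {t.value: 0 for t in MethylationType}
    counts[UNCLASSIFIABLE] = 0
    for xi, yi, zi in zip(x, y, z):
        t = classify_band(LaneTriplet(int(xi), int(yi), int(zi)))
        counts[UNCLASSIFIABLE if t is None else t.value] += 1
    return TypeCounts(sample_id=sample_id, counts=counts)


def type_percentages(c: TypeCounts) -> dict[str, float]:
    """Each type's share of the classifiable bands; sums to exactly 100.

    Each share is ``100 * count / denom`` except the last nonzero one,
    which closes the composition by complement of the running sum so the
    four floats add (in type order) to exactly 100.
    """
    denom = c.n_classifiable
    if denom == 0:
        raise ValueError("no classifiable bands: percentages undefined")
    types = [t.value for t in MethylationType]
    pct = [100.0 * c.counts[t] / denom for t in types]
    k = max(i for i, t in enumerate(types) if c.counts[t] > 0)
    partial = 0.0
    for i in range(k):
        partial += pct[i]
    pct[k] = 100.0 - partial
    return dict(zip(types, pct))


def pattern_ratios_from_counts(c: TypeCounts) -> PatternRatios:
    """Pattern ratios from integer type counts (the formula-faithful path).

    Satisfies exactly: non + total = 100 and total = full + semi.
    """
    denom = c.n_classifiable
    if denom == 0:
        raise ValueError("no classifiable bands: ratios undefined")
    cI = c.counts["I"]
    cII = c.counts["II"]
    cIII = c.counts["III"]
    cIV = c.counts["IV"]
    semi = 100.0 * cII / denom
    full = 100.0 * (cIII + cIV) / denom
    return PatternRatios(
        total_methylation_percent=full + semi,
        full_methylation_percent=full,
        semi_methylation_percent=semi,
        non_methylation_percent=100.0 - (full + semi),
    )


def pattern_ratios_from_percent_vector(
    pI: float, pII: float, pIII: float, pIV: float
) -> PatternRatios:
    """Pattern ratios from published per-type percentages.

    The denominator is taken as 100 (the reading under which published
    ratio rows equal linear sums of the published type rows, even when the
    printed type percentages do not sum exactly to 100):
    total = pII + pIII + pIV, full = pIII + pIV, semi = pII, non = pI.
    """
    if min(pI, pII, pIII, pIV) < 0:
        raise ValueError("type percentages must be non-negative")
    full = pIII + pIV
    return PatternRatios(
        total_methylation_percent=pII + full,
        full_methylation_percent=full,
        semi_methylation_percent=pII,
        non_methylation_percent=pI,
    )


def methylation_table(matrix: BandMatrix, mode: str = "average") -> pd.DataFrame:
    """Per-sample methylation type percentages and pattern ratios.

    Rows: Type I–IV %, total/full/semi/non ratios; columns: samples ordered
    by dose (control first).  ``mode="average"`` computes percentages per
    primer and averages them with equal primer weights (primers whose
    classifiable-band count is zero for a sample are skipped for that
    sample); ``mode="pooled"`` pools counts over primers before dividing.
    All values are unrounded.
    """
    if mode not in ("average", "pooled"):
        raise ValueError("mode must be 'average' or 'pooled'")
    samples = sorted(matrix.samples, key=lambda s: (not s.is_control, s.dose_mg_per_L))
    columns: dict[str, dict[str, float]] = {}
    for s in samples:
        if mode == "pooled":
            c = type_counts(matrix, s.sample_id)
            pct = type_percentages(c)
            ratios = pattern_ratios_from_counts(c)
        else:
            per_primer_pct: list[dict[str, float]] = []
            for primer in matrix.primers:
                c = type_counts(matrix, s.sample_id, primer=primer)
                if c.n_classifiable == 0:
                    continue
                per_primer_pct.append(type_percentages(c))
            if not per_primer_pct:
                raise ValueError(
                    f"sample {s.sample_id!r} has no classifiable bands in any primer"
                )
            k = len(per_primer_pct)
            pct = {
                t.value: sum(p[t.value] for p in per_primer_pct) / k
                for t in MethylationType
            }
            ratios = pattern_ratios_from_percent_vector(
                pct["I"], pct["II"], pct["III"], pct["IV"]
            )
        columns[s.sample_id] = {
            "type_I_percent": pct["I"],
            "type_II_percent": pct["II"],
            "type_III_percent": pct["III"],
            "type_IV_percent": pct["IV"],
            "total_methylation_percent": ratios.total_methylation_percent,
            "full_methylation_percent": ratios.full_methylation_percent,
            "semi_methylation_percent": ratios.semi_methylation_percent,
            "non_methylation_percent": ratios.non_methylation_percent,
        }
    return pd.DataFrame(columns)
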