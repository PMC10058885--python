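"""RAPD polymorphism detection and genomic template stability (GTS).

A treated sample's RAPD profile is compared band-by-band with the control's:
a band present in the treated lane but absent in the control counts as
*appeared*, a band absent in the treated lane but present in the control as
*disappeared*.  With ``a`` the number of polymorphic bands (appeared +
disappeared) and ``n`` the total number of bands present in the control,

    polymorphism % = (a / n) * 100
    GTS %          = (1 - a / n) * 100

GTS is a qualitative genotoxicity index: 100 means the treated template is
indistinguishable from the control, lower values indicate mutational band
changes.  Comparison always uses undigested-template (X) lanes, also for
CRED-RA matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .profiles_io import BandMatrix

__all__ = [
    "PolymorphismSummary",
    "GenotoxResult",
    "gts_percent",
    "polymorphism_percent",
    "detect_polymorphisms",
    "genotox_table",
    "genotox_dataframe",
]

ALL_PRIMERS = "ALL"


@dataclass(frozen=True)
class PolymorphismSummary:
    """Band-change counts for one treated sample against the control.

    ``primer_name`` is a single primer or ``"ALL"`` (counts pooled over
    primers).  ``n`` is the number of bands present in the control for the
    same primer scope.
    """

    sample_id: str
    primer_name: str
    appeared: int
    disappeared: int
    n: int

    @property
    def a(self) -> int:
        return self.appeared + self.disappeared

    def __post_init__(self) -> None:
        if self.appeared < 0 or self.disappeared < 0:
            raise ValueError("band-change counts must be non-negative")
        if self.n < 1:
            raise ValueError("control band count n must be >= 1")
        if self.disappeared > self.n:
            raise ValueError("cannot lose more bands than the control has")


@dataclass(frozen=True)
class GenotoxResult:
    summary: PolymorphismSummary
    polymorphism_percent: float
    gts_percent: float


def gts_percent(a: int, n: int) -> float:
    """Genomic template stability, ``(1 - a/n) * 100``.

    May exceed no bound below 100: with more appearances than control bands
    (``a > n``) the value goes negative and a warning is emitted; the value
    is returned as computed, never clamped.
    """
    if n < 1:
        raise ValueError("n must be a positive count of control bands")
    if a < 0:
        raise ValueError("a must be non-negative")
    if a > n:
        warnings.warn(
            f"a={a} exceeds n={n}; GTS is negative", RuntimeWarning, stacklevel=2
        )
    # computed as the complement of polymorphism% so the two always sum
    # to exactly 100 in floating point
    return 100.0 - (a / n) * 100.0


def polymorphism_percent(a: int, n: int) -> float:
    """Polymorphism rate, ``(a/n) * 100``; complements GTS to exactly 100."""
    if n < 1:
        raise ValueError("n must be a positive count of control bands")
    if a < 0:
        raise ValueError("a must be non-negative")
    return (a / n) * 100.0


def detect_polymorphisms(
    matrix: BandMatrix, sample_id: str, primer: str = ALL_PRIMERS
) -> PolymorphismSummary:
    """Count appeared/disappeared bands of a treated sample vs. the control.

    Raises ``ValueError`` if ``sample_id`` is the control or if the control
    carries no bands in the selected primer scope (n = 0 is undefined), and
    ``KeyError`` for unknown samples or primers.
    """
    sample = matrix.sample(sample_id)
    if sample.is_control:
        raise ValueError("cannot score the control sample against itself")
    control_id = matrix.control.sample_id
    if primer == ALL_PRIMERS:
        bands = matrix.bands
    else:
        bands = matrix.bands_for_primer(primer)
    keys = [b.key for b in bands]
    ctl = matrix.presence.loc[keys, (control_id, "X")].to_numpy()
    trt = matrix.presence.loc[keys, (sample_id, "X")].to_numpy()
    n = int(ctl.sum())
    if n == 0:
        raise ValueError(
            f"control sample has no bands for primer scope {primer!r}; n=0 undefined"
        )
    appeared = int(((trt == 1) & (ctl == 0)).sum())
    disappeared = int(((trt == 0) & (ctl == 1)).sum())
    return PolymorphismSummary(sample_id, primer, appeared, disappeared, n)


def _result(summary: PolymorphismSummary) -> GenotoxResult:
    return GenotoxResult(
        summary=summary,
        polymorphism_percent=polymorphism_percent(summary.a, summary.n),
        gts_percent=gts_percent(summary.a, summary.n),
    )


def genotox_table(matrix: BandMatrix, aggregate: str = "pooled") -> list[GenotoxResult]:
    """Per-(sample, primer) results plus a per-sample all-primer aggregate.

    Treated samples are ordered by dose.  The aggregate row pools counts
    (sum a and n over primers, then divide) when ``aggregate="pooled"``
    (default, the count-consistent reading) or averages per-primer
    percentages with equal weights when ``aggregate="mean"``.
    """
    if aggregate not in ("pooled", "mean"):
        raise ValueError("aggregate must be 'pooled' or 'mean'")
    results: list[GenotoxResult] = []
    treated = sorted(matrix.treated_samples, key=lambda s: s.dose_mg_per_L)
    for sample in treated:
        per_primer: list[PolymorphismSummary] = []
        for primer in matrix.primers:
            try:
                s = detect_polymorphisms(matrix, sample.sample_id, primer)
            except ValueError:
                continue  # control empty for this primer: no denominator
            per_primer.append(s)
            results.append(_result(s))
        if not per_primer:
            continue
        pooled = PolymorphismSummary(
            sample_id=sample.sample_id,
            primer_name=ALL_PRIMERS,
            appeared=sum(s.appeared for s in per_primer),
            disappeared=sum(s.disappeared for s in per_primer),
            n=sum(s.n for s in per_primer),
        )
        if aggregate == "pooled":
            results.append(_result(pooled))
        else:
            poly = sum(polymorphism_percent(s.a, s.n) for s in per_primer) / len(
                per_primer
            )
            results.append(
                GenotoxResult(
                    summary=pooled,
                    polymorphism_percent=poly,
                    gts_percent=100.0 - poly,
                )
            )
    return results


def genotox_dataframe(results: list[GenotoxResult], matrix: BandMatrix) -> pd.DataFrame:
    """Tabular view: sample, dose, primer, a, n, polymorphism %, GTS %."""
    rows = []
    for r in results:
        s = r.summary
        rows.append(
            {
                "sample_id": s.sample_id,
                "dose_mg_per_L": matrix.sample(s.sample_id).dose_mg_per_L,
                "primer": s.primer_name,
                "appeared": s.appeared,
                "disappeared": s.disappeared,
                "a": s.a,
                "n": s.n,
                "polymorphism_percent": r.polymorphism_percent,
                "gts_percent": r.gts_percent,
            }
        )
    return pd.DataFrame(rows)
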