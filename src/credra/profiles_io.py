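"""Band-presence matrices and their TSV exchange format.

Both RAPD and CRED-RA assays score dominant markers: a PCR band is either
present (1) or absent (0) in a lane.  A :class:`BandMatrix` holds these
binary scores over named bands (identified by primer and band id) crossed
with samples and lane kinds.  Lane kinds distinguish the template the band
was amplified from:

``X``
    undigested genomic template,
``H``
    template digested with HpaII (blocked by CpG methylation),
``M``
    template digested with MspI (blocked by external-cytosine methylation).

RAPD matrices carry only ``X`` lanes; CRED-RA matrices carry all three for
every sample.  One schema and one reader/writer serve both assays.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Band",
    "Sample",
    "BandMatrix",
    "BandMatrixError",
    "ParseError",
    "ValidationError",
    "LANE_KINDS",
    "ASSAY_LANES",
    "read_band_matrix",
    "write_band_matrix",
]

LANE_KINDS = ("X", "H", "M")
ASSAY_LANES = {"RAPD": ("X",), "CREDRA": ("X", "H", "M")}

_SIZE_RANGE = (50, 5000)


class BandMatrixError(Exception):
    """Base class for band-matrix errors."""


class ParseError(BandMatrixError):
    """The TSV file does not conform to the band-matrix dialect."""


class ValidationError(BandMatrixError):
    """A structurally parsed matrix violates a model invariant."""


@dataclass(frozen=True)
class Band:
    """One scored PCR band, identified by ``(primer, band_id)``.

    ``size_bp`` is informational metadata (sizing against a ladder); band
    identity across samples is always by id, never by size.
    """

    primer: str
    band_id: str
    size_bp: int | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.primer, self.band_id)


@dataclass(frozen=True)
class Sample:
    """A treatment group lane-set: one control (dose 0) per matrix."""

    sample_id: str
    dose_mg_per_L: float = 0.0
    is_control: bool = False


@dataclass
class BandMatrix:
    """Binary presence/absence of bands over samples and lanes.

    ``presence`` is a DataFrame indexed by ``(primer, band_id)`` with a
    ``(sample_id, lane)`` column MultiIndex and strictly 0/1 integer cells.
    """

    bands: list[Band]
    samples: list[Sample]
    assay: str
    presence: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def lanes(self) -> tuple[str, ...]:
        return ASSAY_LANES[self.assay]

    @property
    def primers(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.bands:
            seen.setdefault(b.primer, None)
        return list(seen)

    @property
    def control(self) -> Sample:
        return next(s for s in self.samples if s.is_control)

    @property
    def treated_samples(self) -> list[Sample]:
        return [s for s in self.samples if not s.is_control]

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"unknown sample {sample_id!r}")

    def get(self, band: Band | tuple[str, str], sample_id: str, lane: str) -> int:
        key = band.key if isinstance(band, Band) else tuple(band)
        return int(self.presence.at[key, (sample_id, lane)])

    def bands_for_primer(self, primer: str) -> list[Band]:
        out = [b for b in self.bands if b.primer == primer]
        if not out:
            raise KeyError(f"unknown primer {primer!r}")
        return out

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.assay not in ASSAY_LANES:
            raise ValidationError(f"unknown assay {self.assay!r}")
        if not self.bands:
            raise ValidationError("matrix has no bands")
        keys = [b.key for b in self.bands]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate (primer, band_id): {dupes}")
        for b in self.bands:
            if b.size_bp is not None and not (
                _SIZE_RANGE[0] <= b.size_bp <= _SIZE_RANGE[1]
            ):
                raise ValidationError(
                    f"band {b.key} size_bp={b.size_bp} outside {_SIZE_RANGE}"
                )
        if not self.samples:
            raise ValidationError("matrix has no samples")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id")
        controls = [s for s in self.samples if s.is_control]
        if len(controls) != 1:
            raise ValidationError(
                f"expected exactly one control sample, found {len(controls)}"
            )
        if controls[0].dose_mg_per_L != 0:
            raise ValidationError("control sample must have dose 0")
        for s in self.samples:
            if s.dose_mg_per_L < 0:
                raise ValidationError(f"sample {s.sample_id!r} has negative dose")

        expected_cols = pd.MultiIndex.from_tuples(
            [(s.sample_id, lane) for s in self.samples for lane in self.lanes]
        )
        if list(self.presence.columns) != list(expected_cols):
            raise ValidationError(
                "presence columns do not match samples × lanes for assay "
                f"{self.assay}"
            )
        if list(self.presence.index) != keys:
            raise ValidationError("presence rows do not match band list")
        values = self.presence.to_numpy()
        if not ((values == 0) | (values == 1)).all():
            raise ValidationError("presence values must be strictly 0 or 1")

    # -- conveniences ------------------------------------------------------

    def rapd_view(self) -> "BandMatrix":
        """Project to X lanes only (a valid RAPD matrix)."""
        cols = [(s.sample_id, "X") for s in self.samples]
        return BandMatrix(
            bands=list(self.bands),
            samples=list(self.samples),
            assay="RAPD",
            presence=self.presence.loc[:, cols].copy(),
        )

    def equals(self, other: "BandMatrix") -> bool:
        return (
            self.assay == other.assay
            and self.bands == other.bands
            and self.samples == other.samples
            and self.presence.equals(other.presence)
        )


def build_matrix(
    bands: Iterable[Band],
    samples: Iterable[Sample],
    assay: str,
    presence: Mapping[tuple[tuple[str, str], str, str], int],
) -> BandMatrix:
    """Assemble a matrix from a ``(band_key, sample_id, lane) -> {0,1}`` map.

    Missing entries default to 0; extra entries raise.
    """
    bands = list(bands)
    samples = list(samples)
    lanes = ASSAY_LANES[assay]
    idx = pd.MultiIndex.from_tuples([b.key for b in bands])
    cols = pd.MultiIndex.from_tuples(
        [(s.sample_id, lane) for s in samples for lane in lanes]
    )
    df = pd.DataFrame(0, index=idx, columns=cols, dtype="int64")
    valid_keys = set(df.index)
    for (band_key, sample_id, lane), v in presence.items():
        if tuple(band_key) not in valid_keys:
            raise ValidationError(f"presence refers to unknown band {band_key}")
        df.at[tuple(band_key), (sample_id, lane)] = int(v)
    return BandMatrix(bands=bands, samples=samples, assay=assay, presence=df)


# ---------------------------------------------------------------------------
# TSV dialect
#
#   # credra-band-matrix v1
#   # assay=CREDRA
#   # sample=<id>  dose_mg_per_L=<float>  control=<true|false>
#   primer  band_id  size_bp  <sample>:<lane>  ...
#   OPC-01  B01      540      1  0  1 ...
#
# UTF-8, tab-separated; '#' comment lines allowed only before the header;
# cells are literal 0/1; size_bp may be NA.
# ---------------------------------------------------------------------------

_MAGIC = "# credra-band-matrix v1"
_SAMPLE_RE = re.compile(
    r"^#\s*sample=(?P<id>\S+)\s+dose_mg_per_L=(?P<dose>\S+)\s+control=(?P<ctl>true|false)\s*$"
)


def write_band_matrix(matrix: BandMatrix, path: str | Path) -> Path:
    """Serialize a validated matrix; round-trips bit-identically."""
    matrix.validate()
    path = Path(path)
    lines = [_MAGIC, f"# assay={matrix.assay}"]
    for s in matrix.samples:
        lines.append(
            f"# sample={s.sample_id} dose_mg_per_L={s.dose_mg_per_L!r} "
            f"control={'true' if s.is_control else 'false'}"
        )
    header = ["primer", "band_id", "size_bp"] + [
        f"{sid}:{lane}" for sid, lane in matrix.presence.columns
    ]
    lines.append("\t".join(header))
    for band in matrix.bands:
        row = [
            band.primer,
            band.band_id,
            "NA" if band.size_bp is None else str(band.size_bp),
        ]
        row += [str(int(v)) for v in matrix.presence.loc[[band.key]].to_numpy()[0]]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_band_matrix(path: str | Path, assay: str | None = None) -> BandMatrix:
    """Parse and validate a band-matrix TSV.

    ``assay`` may be given to assert the expected lane set; by default it is
    taken from the file's ``# assay=`` declaration.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    samples: list[Sample] = []
    declared_assay: str | None = None
    header_cols: list[str] | None = None
    rows: list[tuple[Band, list[int]]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            if header_cols is not None:
                raise ParseError(f"line {lineno}: comment after header")
            m = _SAMPLE_RE.match(line)
            if m:
                try:
                    dose = float(m.group("dose"))
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: bad dose {m.group('dose')!r}") from exc
                samples.append(
                    Sample(m.group("id"), dose, m.group("ctl") == "true")
                )
            elif line.startswith("# assay="):
                declared_assay = line.split("=", 1)[1].strip()
            continue
        cells = line.split("\t")
        if header_cols is None:
            if cells[:3] != ["primer", "band_id", "size_bp"]:
                raise ParseError(
                    f"line {lineno}: malformed header, expected "
                    "'primer\\tband_id\\tsize_bp\\t<sample>:<lane>...'"
                )
            header_cols = cells
            continue
        if len(cells) != len(header_cols):
            raise ParseError(
                f"line {lineno}: expected {len(header_cols)} columns, got {len(cells)}"
            )
        primer, band_id, size_str = cells[:3]
        if size_str == "NA":
            size: int | None = None
        else:
            try:
                size = int(size_str)
            except ValueError as exc:
                raise ParseError(
                    f"line {lineno}: size_bp must be an integer or NA, got {size_str!r}"
                ) from exc
        values: list[int] = []
        for col_idx, cell in enumerate(cells[3:], start=4):
            if cell not in ("0", "1"):
                raise ValidationError(
                    f"non-binary cell at line {lineno}, column {col_idx} "
                    f"({header_cols[col_idx - 1]!r}): {cell!r}"
                )
            values.append(int(cell))
        rows.append((Band(primer, band_id, size), values))

    if header_cols is None:
        raise ParseError("no header row found")
    if not rows:
        raise ValidationError("matrix has no bands")

    resolved_assay = assay or declared_assay
    if resolved_assay is None:
        raise ParseError("no '# assay=' declaration and no assay argument")
    if resolved_assay not in ASSAY_LANES:
        raise ParseError(f"unknown assay {resolved_assay!r}")
    if assay and declared_assay and assay != declared_assay:
        raise ValidationError(
            f"file declares assay {declared_assay!r}, caller expected {assay!r}"
        )

    lane_cols: list[tuple[str, str]] = []
    for col in header_cols[3:]:
        sid, sep, lane = col.partition(":")
        if not sep or lane not in LANE_KINDS:
            raise ParseError(f"malformed lane column {col!r}")
        lane_cols.append((sid, lane))

    if not samples:
        raise ValidationError("missing '# sample=' metadata (no control declared)")
    if not any(s.is_control for s in samples):
        raise ValidationError("no control sample declared")

    expected = [
        (s.sample_id, lane) for s in samples for lane in ASSAY_LANES[resolved_assay]
    ]
    if lane_cols != expected:
        raise ValidationError(
            f"lane columns {lane_cols} do not match declared samples × "
            f"{resolved_assay} lanes"
        )

    idx = pd.MultiIndex.from_tuples([b.key for b, _ in rows])
    cols = pd.MultiIndex.from_tuples(lane_cols)
    df = pd.DataFrame([v for _, v in rows], index=idx, columns=cols, dtype="int64")
    return BandMatrix(
        bands=[b for b, _ in rows], samples=samples, assay=resolved_assay, presence=df
    )
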