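"""Ground-truthed synthetic CRED-RA / RAPD experiments.

The generator replaces the wet lab: it builds random amplicon sequences
carrying a controlled number of CCGG restriction sites, draws a methylation
state for every site in every treatment group, digests in silico with the
HpaII/MspI sensitivity rules, and adds dose-conditioned priming-site
mutations (band loss and band gain) for the genotoxicity channel.  The
hidden truth (per-site states, mutation events) is retained so that
parameter-recovery tests can check the scoring pipeline against what was
actually simulated.

Methylation states per CCGG site:

``U``
    unmethylated — HpaII cuts, MspI cuts (reads out as Type I),
``HE``
    hemi-methylated external cytosine — HpaII cuts, MspI blocked (Type II),
``IF``
    internal cytosine methylated on both strands — HpaII blocked, MspI
    cuts (Type III),
``FF``
    fully methylated — both blocked (Type IV).

A band survives a digestion lane only if *every* CCGG site in its amplicon
blocks that enzyme: a single cut anywhere destroys the full-length
template, so the lane goes dark ("any cleavable site kills the band").

Default per-dose parameters are calibrated to the published summary
statistics for Cu-stressed safflower root tissue: state probabilities are
the reported average methylation-type percentages per dose (normalized to
sum to 1), and the mutation rates are chosen so the expected polymorphic
fraction matches the reported genomic-template-stability rates.  Raw band
counts were never published, so these are distributional calibration
targets, not reproductions.

All randomness flows from one seeded generator with a fixed draw order —
amplicons, then states, then mutations — so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .profiles_io import Band, BandMatrix, Sample, write_band_matrix
from .methylation import MethylationType

__all__ = [
    "STATES",
    "STATE_TO_TYPE",
    "HPAII_BLOCKING_STATES",
    "MSPI_BLOCKING_STATES",
    "RAPD_PRIMERS",
    "REFERENCE_TYPE_PERCENTAGES",
    "REFERENCE_GTS_PERCENT",
    "SimConfig",
    "AmpliconSeq",
    "GainedBand",
    "SyntheticTruth",
    "GenerationError",
    "generate_amplicons",
    "assign_states",
    "digest_and_band",
    "write_truth",
    "simulate",
]

STATES = ("U", "HE", "IF", "FF")

STATE_TO_TYPE = {
    "U": MethylationType.I,
    "HE": MethylationType.II,
    "IF": MethylationType.III,
    "FF": MethylationType.IV,
}

# Which states protect the site from each enzyme (complement = cleavable).
HPAII_BLOCKING_STATES = frozenset({"IF", "FF"})
MSPI_BLOCKING_STATES = frozenset({"HE", "FF"})

# Decamer RAPD primers used for safflower profiling (names kept as band
# namespace labels; sequences are metadata only and are not embedded in the
# simulated amplicons).
RAPD_PRIMERS: Mapping[str, str] = {
    "OPC-01": "TTCGAGCCAG",
    "OPC-02": "GTGAGGCGTC",
    "OPC-04": "CCGCATCTAC",
    "OPC-06": "GAACGGACTC",
    "OPC-07": "GTCCCGACGA",
    "OPC-08": "TGGACCGGTG",
    "OPC-09": "CTCACCGTCC",
    "OPC-10": "TGTCTGGGTG",
    "OPC-11": "AAAGCTGCGG",
    "OPA-08": "GTGACGTAGG",
}

# Published average methylation-type percentages (I, II, III, IV) per Cu
# dose in mg/L; normalized at config construction to give state
# probabilities over (U, HE, IF, FF).
REFERENCE_TYPE_PERCENTAGES: Mapping[float, tuple[float, float, float, float]] = {
    0.0: (2.60, 3.40, 5.10, 86.60),
    20.0: (3.40, 3.60, 7.20, 84.60),
    40.0: (4.10, 3.90, 7.40, 83.00),
    80.0: (7.80, 5.10, 6.60, 81.90),
    160.0: (4.40, 5.60, 5.10, 81.60),
    320.0: (3.40, 3.30, 4.30, 86.80),
    640.0: (2.40, 2.60, 5.30, 86.00),
    1280.0: (2.60, 1.40, 5.90, 85.50),
}

# Published genomic-template-stability rates (%) per dose; the control is
# 100 by definition.  Used to calibrate default mutation rates.
REFERENCE_GTS_PERCENT: Mapping[float, float] = {
    0.0: 100.0,
    20.0: 82.75,
    40.0: 88.90,
    80.0: 86.26,
    160.0: 83.90,
    320.0: 82.25,
    640.0: 84.60,
    1280.0: 83.70,
}

_SEQ_LEN_RANGE = (100, 1000)
_MOTIF = b"CCGG"


class GenerationError(RuntimeError):
    """Sequence construction failed after bounded retries."""


def _default_state_probs(doses: Sequence[float]) -> dict[float, tuple[float, ...]]:
    out = {}
    for d in doses:
        if d not in REFERENCE_TYPE_PERCENTAGES:
            raise ValueError(
                f"no reference type percentages for dose {d}; supply state_probs"
            )
        v = np.asarray(REFERENCE_TYPE_PERCENTAGES[d], dtype=float)
        out[d] = tuple(float(x) for x in v / v.sum())
    return out


def _default_mutation_rates(
    doses: Sequence[float], bands_per_primer: int
) -> tuple[dict[float, float], dict[float, float]]:
    """Split the target polymorphic fraction 2/3 into loss, 1/3 into gain."""
    loss, gain = {}, {}
    for d in doses:
        if d not in REFERENCE_GTS_PERCENT:
            raise ValueError(
                f"no reference GTS for dose {d}; supply band_loss_prob/band_gain_rate"
            )
        p = 1.0 - REFERENCE_GTS_PERCENT[d] / 100.0
        loss[d] = 2.0 * p / 3.0
        gain[d] = (p / 3.0) * bands_per_primer  # expected new bands per primer
    return loss, gain


@dataclass
class SimConfig:
    """Parameters of one simulated dose-ladder experiment.

    ``state_probs`` maps each dose to a probability 4-vector over
    (U, HE, IF, FF); ``band_loss_prob`` is a per-band Bernoulli loss
    probability and ``band_gain_rate`` the Poisson mean of new bands per
    primer, both per dose.  Defaults follow the published calibration
    tables (see module docstring).
    """

    n_primers: int = 10
    bands_per_primer: int = 10
    doses: tuple[float, ...] = (0.0, 20.0, 40.0, 80.0, 160.0, 320.0, 640.0, 1280.0)
    state_probs: Mapping[float, tuple[float, float, float, float]] | None = None
    band_loss_prob: Mapping[float, float] | None = None
    band_gain_rate: Mapping[float, float] | None = None
    sites_per_amplicon: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.doses = tuple(float(d) for d in self.doses)
        if self.n_primers < 1 or self.bands_per_primer < 0:
            raise ValueError("n_primers >= 1 and bands_per_primer >= 0 required")
        if not (1 <= self.sites_per_amplicon <= 20):
            raise ValueError("sites_per_amplicon must be in [1, 20]")
        if len(set(self.doses)) != len(self.doses):
            raise ValueError("doses must be unique")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if sum(d == 0 for d in self.doses) != 1:
            raise ValueError("exactly one dose must be 0 (the control)")
        if self.state_probs is None:
            self.state_probs = _default_state_probs(self.doses)
        else:
            self.state_probs = {float(k): tuple(v) for k, v in self.state_probs.items()}
        default_loss, default_gain = None, None
        if self.band_loss_prob is None or self.band_gain_rate is None:
            default_loss, default_gain = _default_mutation_rates(
                self.doses, self.bands_per_primer
            )
        if self.band_loss_prob is None:
            self.band_loss_prob = default_loss
        else:
            self.band_loss_prob = {float(k): float(v) for k, v in self.band_loss_prob.items()}
        if self.band_gain_rate is None:
            self.band_gain_rate = default_gain
        else:
            self.band_gain_rate = {float(k): float(v) for k, v in self.band_gain_rate.items()}
        for d in self.doses:
            for table, name in (
                (self.state_probs, "state_probs"),
                (self.band_loss_prob, "band_loss_prob"),
                (self.band_gain_rate, "band_gain_rate"),
            ):
                if d not in table:
                    raise ValueError(f"{name} missing an entry for dose {d}")
            v = np.asarray(self.state_probs[d], dtype=float)
            if v.shape != (4,) or (v < 0).any() or (v > 1).any():
                raise ValueError(f"state_probs[{d}] must be 4 probabilities")
            if abs(v.sum() - 1.0) > 1e-12:
                raise ValueError(f"state_probs[{d}] must sum to 1 (got {v.sum()!r})")
            if not (0 <= self.band_loss_prob[d] <= 1):
                raise ValueError(f"band_loss_prob[{d}] must be in [0, 1]")
            if self.band_gain_rate[d] < 0:
                raise ValueError(f"band_gain_rate[{d}] must be >= 0")

    # -- naming ------------------------------------------------------------

    def primer_names(self) -> list[str]:
        base = list(RAPD_PRIMERS)
        if self.n_primers <= len(base):
            return base[: self.n_primers]
        extra = [f"SIM-{i:02d}" for i in range(len(base) + 1, self.n_primers + 1)]
        return base + extra

    def sample_id(self, dose: float) -> str:
        return "control" if dose == 0 else f"Cu{dose:g}"

    def samples(self) -> list[Sample]:
        return [
            Sample(self.sample_id(d), dose_mg_per_L=d, is_control=(d == 0))
            for d in self.doses
        ]

    # -- (de)serialization for CLI config files ----------------------------

    def to_dict(self) -> dict:
        return {
            "n_primers": self.n_primers,
            "bands_per_primer": self.bands_per_primer,
            "doses": list(self.doses),
            "state_probs": {
                float(k): [float(x) for x in v] for k, v in self.state_probs.items()
            },
            "band_loss_prob": {float(k): float(v) for k, v in self.band_loss_prob.items()},
            "band_gain_rate": {float(k): float(v) for k, v in self.band_gain_rate.items()},
            "sites_per_amplicon": self.sites_per_amplicon,
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass(frozen=True)
class AmpliconSeq:
    """A simulated full-length PCR product with its CCGG site offsets."""

    primer: str
    band_id: str
    sequence: str
    ccgg_offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        for off in self.ccgg_offsets:
            if self.sequence[off : off + 4] != "CCGG":
                raise ValueError(f"offset {off} does not point at CCGG")
        if self.sequence.count("CCGG") != len(self.ccgg_offsets):
            raise ValueError("sequence carries unregistered CCGG occurrences")


@dataclass(frozen=True)
class GainedBand:
    """A de novo band that appeared in one treated sample only."""

    sample_id: str
    amplicon: AmpliconSeq
    states: tuple[str, ...]


@dataclass
class SyntheticTruth:
    """Hidden ground truth of one simulated experiment.

    ``states`` maps ``(sample_id, primer, band_id)`` to the per-site state
    tuple; ``lost`` flags (sample, band) pairs whose band was mutated away.
    """

    states: dict[tuple[str, str, str], tuple[str, ...]] = field(default_factory=dict)
    lost: set[tuple[str, str, str]] = field(default_factory=set)
    gained: list[GainedBand] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq_without_motif(rng: np.random.Generator, length: int) -> bytearray:
    seq = bytearray(_BASE_BYTES[rng.integers(0, 4, size=length)].tobytes())
    # CCGG contains no A, so rewriting one G to A kills an occurrence
    # without being able to seed a new one.
    for _ in range(200):
        i = bytes(seq).find(_MOTIF)
        if i < 0:
            return seq
        seq[i + 2] = ord("A")
    raise GenerationError("could not scrub accidental CCGG motifs")


def _pick_offsets(rng: np.random.Generator, length: int, k: int) -> list[int]:
    hi = length - 4
    for _ in range(1000):
        offs = sorted(int(o) for o in rng.integers(0, hi + 1, size=k))
        if all(b - a >= 4 for a, b in zip(offs, offs[1:])):
            return offs
    raise GenerationError(f"could not place {k} non-overlapping sites in {length} bp")


def _make_amplicon(
    rng: np.random.Generator, primer: str, band_id: str, k: int
) -> AmpliconSeq:
    length = int(rng.integers(_SEQ_LEN_RANGE[0], _SEQ_LEN_RANGE[1] + 1))
    seq = _random_seq_without_motif(rng, length)
    offs = _pick_offsets(rng, length, k)
    for off in offs:
        seq[off : off + 4] = _MOTIF
    s = seq.decode("ascii")
    if s.count("CCGG") != k:
        raise GenerationError("site insertion produced a wrong motif count")
    return AmpliconSeq(primer=primer, band_id=band_id, sequence=s, ccgg_offsets=tuple(offs))


def generate_amplicons(
    cfg: SimConfig, rng: np.random.Generator
) -> list[AmpliconSeq]:
    """One amplicon per (primer, band), each with exactly
    ``cfg.sites_per_amplicon`` CCGG sites and no accidental extras."""
    out: list[AmpliconSeq] = []
    for primer in cfg.primer_names():
        for j in range(cfg.bands_per_primer):
            out.append(_make_amplicon(rng, primer, f"B{j + 1:03d}", cfg.sites_per_amplicon))
    return out


# ---------------------------------------------------------------------------
# state assignment and mutation events
# ---------------------------------------------------------------------------


def assign_states(
    cfg: SimConfig, amplicons: list[AmpliconSeq], rng: np.random.Generator
) -> SyntheticTruth:
    """Draw per-site methylation states, then loss/gain mutation events.

    Every site draws independently from its dose's state distribution;
    band loss is Bernoulli per (band, sample) and band gain Poisson per
    (primer, sample), with the control (dose 0) using the dose-0 rates.
    Gained bands receive their own amplicons and state draws.
    """
    truth = SyntheticTruth()
    for dose in cfg.doses:
        sid = cfg.sample_id(dose)
        cum = np.cumsum(np.asarray(cfg.state_probs[dose], dtype=float))
        for amp in amplicons:
            u = rng.random(len(amp.ccgg_offsets))
            idx = np.minimum(np.searchsorted(cum, u, side="right"), 3)
            truth.states[(sid, amp.primer, amp.band_id)] = tuple(STATES[i] for i in idx)
    for dose in cfg.doses:
        sid = cfg.sample_id(dose)
        q = cfg.band_loss_prob[dose]
        g = cfg.band_gain_rate[dose]
        if q > 0:
            draws = rng.random(len(amplicons))
            for amp, u in zip(amplicons, draws):
                if u < q:
                    truth.lost.add((sid, amp.primer, amp.band_id))
        if g > 0:
            cum = np.cumsum(np.asarray(cfg.state_probs[dose], dtype=float))
            for primer in cfg.primer_names():
                for j in range(int(rng.poisson(g))):
                    band_id = f"G-{sid}-{j + 1:03d}"
                    amp = _make_amplicon(rng, primer, band_id, cfg.sites_per_amplicon)
                    u = rng.random(len(amp.ccgg_offsets))
                    idx = np.minimum(np.searchsorted(cum, u, side="right"), 3)
                    states = tuple(STATES[i] for i in idx)
                    truth.states[(sid, primer, band_id)] = states
                    truth.gained.append(GainedBand(sid, amp, states))
    return truth


# ---------------------------------------------------------------------------
# in-silico digestion and banding
# ---------------------------------------------------------------------------


def _lane_bits(states: tuple[str, ...]) -> tuple[int, int]:
    """(H, M) presence of a band given its per-site states: the band
    survives a digestion lane only if every site blocks that enzyme."""
    h = int(all(s in HPAII_BLOCKING_STATES for s in states))
    m = int(all(s in MSPI_BLOCKING_STATES for s in states))
    return h, m


def digest_and_band(
    truth: SyntheticTruth, amplicons: list[AmpliconSeq], cfg: SimConfig
) -> BandMatrix:
    """Apply the enzyme rules and mutation events; emit a CRED-RA matrix.

    Base bands present X=1 in every sample unless lost; gained bands are
    present only in their own sample.  H and M lanes follow the
    any-cleavable-site rule on the drawn states.
    """
    samples = cfg.samples()
    all_amplicons = list(amplicons) + [gb.amplicon for gb in truth.gained]
    gained_keys = {(gb.amplicon.primer, gb.amplicon.band_id): gb for gb in truth.gained}
    bands = [
        Band(a.primer, a.band_id, size_bp=len(a.sequence)) for a in all_amplicons
    ]
    idx = pd.MultiIndex.from_tuples([b.key for b in bands])
    cols = pd.MultiIndex.from_tuples(
        [(s.sample_id, lane) for s in samples for lane in ("X", "H", "M")]
    )
    data = np.zeros((len(bands), len(cols)), dtype="int64")
    col_pos = {c: i for i, c in enumerate(cols)}
    for r, amp in enumerate(all_amplicons):
        key = (amp.primer, amp.band_id)
        gb = gained_keys.get(key)
        for s in samples:
            sid = s.sample_id
            if gb is not None:
                if sid != gb.sample_id:
                    continue  # de novo band absent elsewhere
                states = gb.states
            else:
                if (sid, amp.primer, amp.band_id) in truth.lost:
                    continue  # mutated away: dark in every lane
                states = truth.states[(sid, amp.primer, amp.band_id)]
            h, m = _lane_bits(states)
            data[r, col_pos[(sid, "X")]] = 1
            data[r, col_pos[(sid, "H")]] = h
            data[r, col_pos[(sid, "M")]] = m
    presence = pd.DataFrame(data, index=idx, columns=cols)
    return BandMatrix(bands=bands, samples=samples, assay="CREDRA", presence=presence)


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------


def write_truth(truth: SyntheticTruth, path: str | Path) -> Path:
    """Hidden truth as TSV: one row per (sample, band, site)."""
    path = Path(path)
    gained_pairs = {(gb.sample_id, gb.amplicon.primer, gb.amplicon.band_id) for gb in truth.gained}
    lines = ["sample_id\tprimer\tband_id\tsite_index\tstate\tlost\tgained"]
    for (sid, primer, band_id), states in truth.states.items():
        lost = int((sid, primer, band_id) in truth.lost)
        gained = int((sid, primer, band_id) in gained_pairs)
        for i, st in enumerate(states):
            lines.append(f"{sid}\t{primer}\t{band_id}\t{i}\t{st}\t{lost}\t{gained}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_amplicons_fasta(
    amplicons: list[AmpliconSeq], truth: SyntheticTruth, path: str | Path
) -> Path:
    path = Path(path)
    records = [
        SeqRecord(
            Seq(a.sequence),
            id=f"{a.primer}|{a.band_id}|{len(a.sequence)}",
            description="",
        )
        for a in list(amplicons) + [gb.amplicon for gb in truth.gained]
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path


def simulate(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run the full generator and write all artifacts.

    Writes ``credra.tsv`` (full matrix), ``rapd.tsv`` (X-lane projection),
    ``truth.tsv`` and ``amplicons.fasta``; fully deterministic per seed.
    Returns the path of each artifact.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    amplicons = generate_amplicons(cfg, rng)
    truth = assign_states(cfg, amplicons, rng)
    matrix = digest_and_band(truth, amplicons, cfg)
    paths = {
        "credra": write_band_matrix(matrix, out_dir / "credra.tsv"),
        "rapd": write_band_matrix(matrix.rapd_view(), out_dir / "rapd.tsv"),
        "truth": write_truth(truth, out_dir / "truth.tsv"),
        "amplicons": write_amplicons_fasta(amplicons, truth, out_dir / "amplicons.fasta"),
    }
    return paths
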