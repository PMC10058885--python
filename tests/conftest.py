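import pandas as pd
import pytest
from hypothesis import strategies as st

from credra.profiles_io import Band, BandMatrix, Sample, build_matrix


@pytest.fixture
def rapd_matrix() -> BandMatrix:
    """1 primer, 4 known bands; control carries b1-b3, treated carries b1,b4.

    Against the control this gives appeared=1 (b4), disappeared=2 (b2, b3),
    a=3, n=3.
    """
    bands = [Band("OPC-01", f"b{i}") for i in range(1, 5)]
    samples = [Sample("control", 0.0, True), Sample("Cu20", 20.0, False)]
    presence = {}
    for b in ("b1", "b2", "b3"):
        presence[(("OPC-01", b), "control", "X")] = 1
    for b in ("b1", "b4"):
        presence[(("OPC-01", b), "Cu20", "X")] = 1
    return build_matrix(bands, samples, "RAPD", presence)


@pytest.fixture
def two_primer_matrix() -> BandMatrix:
    """2 primers x 5 control bands each; treated loses one band per primer."""
    bands = [Band(p, f"b{i}") for p in ("P1", "P2") for i in range(1, 6)]
    samples = [Sample("control", 0.0, True), Sample("Cu40", 40.0, False)]
    presence = {}
    for b in bands:
        presence[(b.key, "control", "X")] = 1
        presence[(b.key, "Cu40", "X")] = 0 if b.band_id == "b1" else 1
    return build_matrix(bands, samples, "RAPD", presence)


@pytest.fixture
def credra_matrix() -> BandMatrix:
    """CRED-RA matrix whose treated sample shows one band of each type.

    Triplets for Cu20: (1,0,0), (1,0,1), (1,1,0), (1,1,1) over bands b1-b4;
    the control shows all four bands fully methylated (1,1,1).
    """
    bands = [Band("OPC-01", f"b{i}") for i in range(1, 5)]
    samples = [Sample("control", 0.0, True), Sample("Cu20", 20.0, False)]
    triplets = {"b1": (1, 0, 0), "b2": (1, 0, 1), "b3": (1, 1, 0), "b4": (1, 1, 1)}
    presence = {}
    for b in bands:
        for lane in ("X", "H", "M"):
            presence[(b.key, "control", lane)] = 1
        x, h, m = triplets[b.band_id]
        presence[(b.key, "Cu20", "X")] = x
        presence[(b.key, "Cu20", "H")] = h
        presence[(b.key, "Cu20", "M")] = m
    return build_matrix(bands, samples, "CREDRA", presence)


@st.composite
def band_matrices(draw, assay: str | None = None) -> BandMatrix:
    """Random valid matrices: 1-3 primers, 1-4 bands each, 1-4 samples."""
    from credra.profiles_io import ASSAY_LANES

    assay = assay or draw(st.sampled_from(["RAPD", "CREDRA"]))
    lanes = ASSAY_LANES[assay]
    n_primers = draw(st.integers(1, 3))
    bands = []
    for p in range(n_primers):
        n_bands = draw(st.integers(1, 4))
        for b in range(n_bands):
            size = draw(st.none() | st.integers(50, 5000))
            bands.append(Band(f"P{p + 1}", f"b{b + 1}", size))
    n_treated = draw(st.integers(0, 3))
    doses = draw(
        st.lists(
            st.floats(0.001, 2000, allow_nan=False), min_size=n_treated,
            max_size=n_treated, unique=True,
        )
    )
    samples = [Sample("control", 0.0, True)] + [
        Sample(f"S{i + 1}", d, False) for i, d in enumerate(doses)
    ]
    presence = {}
    for band in bands:
        for s in samples:
            for lane in lanes:
                presence[(band.key, s.sample_id, lane)] = draw(st.integers(0, 1))
    return build_matrix(bands, samples, assay, presence)
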