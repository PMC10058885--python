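"""Score polymorphisms and genomic template stability on a tiny matrix.

A control lane with three bands is compared against a treated lane that
lost two of them and gained a new one; GTS quantifies how disturbed the
treated genome's amplification template is.
"""

from credra import Band, Sample, detect_polymorphisms, gts_percent
from credra.profiles_io import build_matrix

bands = [Band("OPC-01", b) for b in ("b1", "b2", "b3", "b4")]
samples = [Sample("control", 0.0, True), Sample("Cu320", 320.0, False)]
presence = {
    (("OPC-01", "b1"), "control", "X"): 1,
    (("OPC-01", "b2"), "control", "X"): 1,
    (("OPC-01", "b3"), "control", "X"): 1,
    (("OPC-01", "b1"), "Cu320", "X"): 1,
    (("OPC-01", "b4"), "Cu320", "X"): 1,
}
matrix = build_matrix(bands, samples, "RAPD", presence)

s = detect_polymorphisms(matrix, "Cu320", "OPC-01")
print(f"control bands n={s.n}; appeared={s.appeared}, disappeared={s.disappeared}")
print(f"polymorphic bands a = {s.a}")
print(f"GTS = (1 - a/n) x 100 = {gts_percent(s.a, s.n):.2f} %")
print("GTS of 0 % means every control band changed: maximal genotoxic "
      "signal; 100 % would mean a profile identical to the control.")
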