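"""Charge-based developability descriptors from heavy/light chain sequences.

Computes per-chain net charges at formulation pH 6, the Fv charge symmetry
parameter FvCSP = q_VL x q_VH, the chain imbalance Fv_chml = q_VH - q_VL,
and the sequence isoelectric point. A negative FvCSP signals opposite-sign
chain charges (charge asymmetry), which correlates with elevated viscosity
at high antibody concentration; Fv_chml keeps resolving chain imbalance
even when one chain's charge crosses zero and FvCSP collapses to 0.
"""

import patchscreen as ps

# short illustrative variable-domain sequences (not a real antibody)
vl = "DIQMTQSPSSLSASVGDRVTITCRASQDEDSYLN"
vh = "EVQLVESGGGLVQPGGSLRLSCAASGFTKKFSSYAMS"

pH = 6.0
q_vl = ps.net_charge(vl, pH)
q_vh = ps.net_charge(vh, pH)

print(f"q_VL at pH {pH}: {q_vl:+.2f} e")
print(f"q_VH at pH {pH}: {q_vh:+.2f} e")
print(f"FvCSP  = {ps.fv_csp(q_vl, q_vh):+.2f} e²")
print(f"Fv_chml = {ps.fv_chml(q_vl, q_vh):+.2f} e")
print(f"pI (sequence) = {ps.isoelectric_point(vl + vh):.2f}")

# the degenerate case the product descriptor cannot see:
print("FvCSP with a zero-charge chain:", ps.fv_csp(0.0, q_vh))
print("Fv_chml still reports imbalance:", round(ps.fv_chml(0.0, q_vh), 2))
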