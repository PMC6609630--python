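"""Derive PBPK enzyme kinetics from clinical clearance (packaged assets).

Loads the packaged lamotrigine parameters and adult physiology, then runs
the well-stirred IVIVE chain: hepatic clearance -> unbound intrinsic hepatic
clearance -> per-isoform partition -> in vitro CL_int -> Vmax.
"""

from dmetpk import (
    data_path,
    derive_enzyme_kinetics,
    kinetics_table,
    load_drug,
    load_enzyme_table,
    load_physiology,
)

drug = load_drug(data_path("lamotrigine.yaml"))
phys = load_physiology(data_path("adult.yaml"))
kins = load_enzyme_table(data_path("lamotrigine_enzymes.csv"))

cluint_h, kins = derive_enzyme_kinetics(drug, phys, kins)

print(f"drug: {drug.name}")
print(f"CL_IV = {drug.CL_IV} L/h -> CL_R = {drug.CL_R:.2f} L/h, "
      f"CL_H = {drug.CL_H:.2f} L/h")
print(f"well-stirred back-calculation: CLu_int,H = {cluint_h:.2f} L/h")
print(kinetics_table(kins).round(4).to_string(index=False))

# Vmax (pmol/min per pmol enzyme) and Km are the quantities a PBPK
# simulator's enzyme module consumes; the CLu_int column is the whole-liver
# clearance each isoform accounts for.
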