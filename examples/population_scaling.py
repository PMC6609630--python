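"""Scale adult enzyme kinetics to special populations.

Three scalings are shown: (a) variability bounds from the pooled-abundance
confidence interval, (b) hepatic impairment via disease-reduced enzyme
abundance, and (c) a paediatric liver via liver weight, plus renal-clearance
scaling by fu*GFR (paediatric GFR/fu supplied explicitly here, since no
published value ships with the package).
"""

from dmetpk import (
    EnzymeKinetics,
    Physiology,
    PopulationSpec,
    ScaleFactorSet,
    adjust_vmax,
    data_path,
    derive_enzyme_kinetics,
    load_drug,
    load_enzyme_table,
    load_physiology,
    load_population,
    scale_clr,
    scaled_cluint,
    sf_ci,
    sf_population,
)

drug = load_drug(data_path("lamotrigine.yaml"))
adult_phys = load_physiology(data_path("adult.yaml"))
adult = load_population(data_path("adult.yaml"))
kins = load_enzyme_table(data_path("lamotrigine_enzymes.csv"))
_, kins = derive_enzyme_kinetics(drug, adult_phys, kins)
ugt1a4 = next(k for k in kins if k.enzyme == "UGT1A4")

# (a) variability bounds from the pooled abundance 95% CI
mean, lo, hi = adult.enzyme_abundance["UGT1A4_pooled"]
for tag, bound in (("lower", lo), ("upper", hi)):
    sf = ScaleFactorSet(provenance=f"UGT1A4 pooled {tag} 95% CI",
                        SF_CI=sf_ci(bound, mean))
    vmax = adjust_vmax(ugt1a4.Vmax_pmol_min_pmol, sf, mode="ci")
    print(f"{tag} abundance bound: SF_CI = {sf.SF_CI:.4f} "
          f"-> Vmax = {vmax:.2f} pmol/min/pmol")

# (b) hepatic impairment (Child-Pugh C) via reduced UGT1A4 abundance
for asset in ("hi_child_pugh_c_alcoholic.yaml", "hi_child_pugh_c_hcv.yaml"):
    pop = load_population(data_path(asset))
    sf_dme, sf_mppgl = sf_population(pop, adult, "UGT1A4_pooled")
    sf = ScaleFactorSet(provenance=pop.label, SF_DME=sf_dme,
                        SF_MPPGL=sf_mppgl)
    vmax = adjust_vmax(ugt1a4.Vmax_pmol_min_pmol, sf, mode="population")
    hi_phys = Physiology(label=pop.label, Q_HB=adult_phys.Q_HB,
                         MPPGL=pop.MPPGL, liver_weight_g=pop.liver_weight_g)
    cluint = scaled_cluint(vmax, ugt1a4, hi_phys, drug.fu_mic)
    print(f"{pop.label}: SF_DME = {sf_dme:.4f} -> Vmax = {vmax:.2f}, "
          f"scaled CLu_int = {cluint:.3f} L/h")

# (c) paediatric liver (7 y): same per-mg kinetics, smaller liver, and
# renal clearance scaled by fu*GFR with explicitly supplied values
child = load_population(data_path("children.yaml"))
child.fu_p = 0.45          # fraction unbound, assumed equal to adult
child.GFR = 100.0          # mL/min, user-supplied estimate
child_phys = Physiology(label=child.label, Q_HB=adult_phys.Q_HB,
                        MPPGL=child.MPPGL,
                        liver_weight_g=child.liver_weight_g)
cluint_child = scaled_cluint(ugt1a4.Vmax_pmol_min_pmol, ugt1a4, child_phys,
                             drug.fu_mic)
clr_child = scale_clr(drug.CL_R, child, adult)
print(f"{child.label}: liver {child.liver_weight_g} g -> "
      f"CLu_int = {cluint_child:.3f} L/h "
      f"(x{child.liver_weight_g / adult_phys.liver_weight_g:.3f} of adult), "
      f"CL_R = {clr_child:.3f} L/h")

# The adjusted Vmax / scaled CLu_int / scaled CL_R triplet is what changes
# between populations in a PBPK run; everything else stays drug-specific.
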