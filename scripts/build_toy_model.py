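"""Regenerate the packaged toy nitrogen network (src/nitrosense/data/ptoy_nitrogen.json).

Run from the repository root. The stoichiometry is asserted C/N-balanced
before writing.
"""
import json
from pathlib import Path

MET = {}
def met(mid, comp, C, N):
    MET[mid] = {"id": mid, "compartment": comp, "C": C, "N": N}

for comp in ("e",):
    met("no3_e","e",0,1); met("urea_e","e",1,2); met("o2_e","e",0,0); met("co2_e","e",1,0)
met("no3_c","c",0,1); met("no2_c","c",0,1); met("nh4_c","c",0,1)
met("glu_c","c",5,1); met("gln_c","c",5,2); met("asp_c","c",4,1); met("ala_c","c",3,1)
met("arg_c","c",6,4); met("citr_c","c",6,3); met("fum_c","c",4,0); met("gap_c","c",3,0)
met("co2_c","c",1,0); met("pro_c","c",5,1); met("orn_c","c",5,2); met("urea_c","c",1,2)
met("no2_h","h",0,1); met("nh4_h","h",0,1); met("glu_h","h",5,1); met("gln_h","h",5,2)
met("akg_h","h",5,0); met("asp_h","h",4,1); met("ala_h","h",3,1); met("oaa_h","h",4,0)
met("pyr_h","h",3,0); met("gap_h","h",3,0); met("orn_h","h",5,2); met("co2_h","h",1,0); met("o2_h","h",0,0)
met("nh4_m","m",0,1); met("glu_m","m",5,1); met("gln_m","m",5,2); met("akg_m","m",5,0)
met("asp_m","m",4,1); met("ala_m","m",3,1); met("oaa_m","m",4,0); met("pyr_m","m",3,0)
met("gap_m","m",3,0); met("orn_m","m",5,2); met("cp_m","m",1,1); met("citr_m","m",6,3)
met("fum_m","m",4,0); met("urea_m","m",1,2); met("co2_m","m",1,0); met("o2_m","m",0,0)

RXN = []
def rxn(rid, stoich, lb=0.0, ub=1000.0, typ="internal"):
    RXN.append({"id": rid, "stoichiometry": stoich, "lb": lb, "ub": ub, "type": typ})

# exchanges (nitrate scenario open by default)
rxn("EX_no3_e", {"no3_e": -1}, -10, 0, "exchange")
rxn("EX_urea_e", {"urea_e": -1}, 0, 0, "exchange")
rxn("EX_o2_e", {"o2_e": -1}, 0, 1000, "exchange")
rxn("EX_co2_e", {"co2_e": -1}, -1000, 1000, "exchange")
# nitrate assimilation (chloroplast)
rxn("NO3t_ec", {"no3_e": -1, "no3_c": 1})
rxn("NR_c", {"no3_c": -1, "no2_c": 1})
rxn("NO2t_ch", {"no2_c": -1, "no2_h": 1})
rxn("NiR_h", {"no2_h": -1, "nh4_h": 1})
rxn("GSII_h", {"glu_h": -1, "nh4_h": -1, "gln_h": 1})
rxn("GOGAT_h", {"gln_h": -1, "akg_h": -1, "glu_h": 2})
# urea assimilation (mitochondrion)
rxn("UREAt_em", {"urea_e": -1, "urea_m": 1})
rxn("URE_m", {"urea_m": -1, "nh4_m": 2, "co2_m": 1})
rxn("GSIII_m", {"glu_m": -1, "nh4_m": -1, "gln_m": 1})
rxn("GOGAT_m", {"gln_m": -1, "akg_m": -1, "glu_m": 2})
rxn("GDH_m", {"glu_m": -1, "akg_m": 1, "nh4_m": 1})
# transaminase shuttles
rxn("AST_h", {"glu_h": -1, "oaa_h": -1, "akg_h": 1, "asp_h": 1})
rxn("AST_m", {"asp_m": -1, "akg_m": -1, "oaa_m": 1, "glu_m": 1})
rxn("ALT_m", {"glu_m": -1, "pyr_m": -1, "akg_m": 1, "ala_m": 1})
rxn("ALT_h", {"ala_h": -1, "akg_h": -1, "pyr_h": 1, "glu_h": 1})
# carbon backbone
rxn("PSFIX_h", {"co2_h": -3, "gap_h": 1, "o2_h": 3})
rxn("GLYC_m", {"gap_m": -1, "pyr_m": 1})
rxn("PYC_h", {"pyr_h": -1, "co2_h": -1, "oaa_h": 1})
rxn("PYC_m", {"pyr_m": -1, "co2_m": -1, "oaa_m": 1})
rxn("AKGS_m", {"oaa_m": -1, "pyr_m": -1, "akg_m": 1, "co2_m": 2})
rxn("FUM2OAA_m", {"fum_m": -1, "oaa_m": 1})
# ornithine / urea cycle (arginine synthesis split across organelles)
rxn("ORNS_h", {"glu_h": -2, "orn_h": 1, "akg_h": 1})
rxn("CPS_m", {"nh4_m": -1, "co2_m": -1, "cp_m": 1})
rxn("OTC_m", {"orn_m": -1, "cp_m": -1, "citr_m": 1})
rxn("ASS_ASL_c", {"citr_c": -1, "asp_c": -1, "arg_c": 1, "fum_c": 1})
rxn("ARGASE_c", {"arg_c": -1, "orn_c": 1, "urea_c": 1}, 0, 0)
rxn("PROS_c", {"glu_c": -1, "pro_c": 1})
# maintenance
rxn("AOX_m", {"o2_m": -1}, 0, 1.0)
# transporters
rxn("GAPt_hm", {"gap_h": -1, "gap_m": 1})
rxn("GAPt_hc", {"gap_h": -1, "gap_c": 1})
rxn("PYRt_mh", {"pyr_m": -1, "pyr_h": 1}, -1000, 1000)
rxn("ASPt_hm", {"asp_h": -1, "asp_m": 1})
rxn("ASPt_hc", {"asp_h": -1, "asp_c": 1})
rxn("ALAt_mh", {"ala_m": -1, "ala_h": 1})
rxn("ALAt_mc", {"ala_m": -1, "ala_c": 1})
rxn("GLUt_hc", {"glu_h": -1, "glu_c": 1})
rxn("GLUt_mc", {"glu_m": -1, "glu_c": 1})
rxn("GLNt_hc", {"gln_h": -1, "gln_c": 1})
rxn("GLNt_mc", {"gln_m": -1, "gln_c": 1})
rxn("GLUt_hm", {"glu_h": -1, "glu_m": 1}, -0.01, 0.01)
rxn("GLNt_hm", {"gln_h": -1, "gln_m": 1}, -0.01, 0.01)
rxn("NH4t_hc", {"nh4_h": -1, "nh4_c": 1}, -1000, 1000)
rxn("NH4t_mc", {"nh4_m": -1, "nh4_c": 1}, -1000, 1000)
rxn("AKGt_mh", {"akg_m": -1, "akg_h": 1}, -1000, 1000)
rxn("ORNt_hm", {"orn_h": -1, "orn_m": 1})
rxn("ORNt_cm", {"orn_c": -1, "orn_m": 1})
rxn("UREAt_cm", {"urea_c": -1, "urea_m": 1})
rxn("CITRt_mc", {"citr_m": -1, "citr_c": 1})
rxn("FUMt_cm", {"fum_c": -1, "fum_m": 1})
rxn("O2t_he", {"o2_h": -1, "o2_e": 1})
rxn("O2t_hm", {"o2_h": -1, "o2_m": 1})
rxn("CO2t_ec", {"co2_e": -1, "co2_c": 1}, -1000, 1000)
rxn("CO2t_ch", {"co2_c": -1, "co2_h": 1}, -1000, 1000)
rxn("CO2t_cm", {"co2_c": -1, "co2_m": 1}, -1000, 1000)
# biomass
rxn("bof_c", {"glu_c": -0.3, "gln_c": -0.2, "asp_c": -0.2, "ala_c": -0.2,
              "arg_c": -0.1, "gap_c": -1.0}, 0, 1000, "biomass")

doc = {
    "id": "ptoy_nitrogen",
    "notes": (
        "Hand-built toy compartmentalized nitrogen network for a diatom cell "
        "(extracellular e, cytosol c, chloroplast h, mitochondrion m). Carbon and "
        "nitrogen atom counts are annotated per metabolite and every internal "
        "reaction is elementally balanced. The network is deliberately engineered "
        "so that the qualitative inter-organelle shuttle behavior is identifiable: "
        "aspartate is only synthesized in the chloroplast (AST_h) and consumed in "
        "the mitochondrion (AST_m), alanine only synthesized in the mitochondrion "
        "(ALT_m) and consumed in the chloroplast (ALT_h), direct glutamate/"
        "glutamine transport between the organelles is capacity-restricted "
        "(GLUt_hm, GLNt_hm), ammonium transport is capped at run time, and the "
        "chloroplast demands pyruvate (PYC_h) for oxaloacetate synthesis. The "
        "arginase reaction (the catabolic arm of the urea cycle) is closed by "
        "default because the simulations capture only the anabolic phase. Growth "
        "is carbon/O2-limited through photosynthetic GAP production."
    ),
    "compartments": {"e": "extracellular", "c": "cytosol",
                     "h": "chloroplast", "m": "mitochondrion"},
    "metabolites": list(MET.values()),
    "reactions": RXN,
    "objective": "bof_c",
}
out = Path("src/nitrosense/data/ptoy_nitrogen.json")
out.write_text(json.dumps(doc, indent=1))
print("reactions:", len(RXN), "metabolites:", len(MET))

# quick balance check
for r in RXN:
    if r["type"] != "internal":
        continue
    for e in ("C", "N"):
        bal = sum(c * MET[m][e] for m, c in r["stoichiometry"].items())
        assert abs(bal) < 1e-9, (r["id"], e, bal)
print("balanced OK")
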