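"""Published reference constants for the GlpG peptidyl-ketoamide series.

Literature-reported kinetic and screening values for the characterized
rhomboid-protease (GlpG) inhibitors. These serve two purposes: as the
generating parameters of the synthetic world (the simulators default to
the reported constants) and as the expected values of in-literature
arithmetic such as potency fold-changes along the N-terminal truncation
series.

The reported kon column (10⁻⁶ nM⁻¹·min⁻¹) is internally inconsistent with
Ki = koff/kon by roughly a factor of ten, so (Ki, koff) are treated as the
authoritative pair and kon is always derived as koff/Ki.
"""

from __future__ import annotations

from .schemes import KineticScheme, Modality

# Ki (nM), koff (min⁻¹), reported kon (nM⁻¹·min⁻¹; NOT used to build
# schemes, see module docstring), in vivo IC50 against E. coli GlpG (nM).
COMPOUND_CONSTANTS = {
    "9": {"Ki_nM": 220.0, "Ki_sd": 80.0, "koff": 12.0e-3, "koff_sd": 0.4e-3,
          "kon_reported": 5.7e-6, "ic50_vivo_nM": 8.8},
    "10": {"Ki_nM": 120.0, "Ki_sd": 50.0, "koff": 4.2e-3, "koff_sd": 1.4e-3,
           "kon_reported": 3.4e-6, "ic50_vivo_nM": 6.0},
    "11": {"Ki_nM": 45.0, "Ki_sd": 8.0, "koff": 3.9e-3, "koff_sd": 0.6e-3,
           "kon_reported": 8.7e-6, "ic50_vivo_nM": 2.7},
}

#: Apparent inhibitory constant of compound 10 from the progress-curve
#: analysis (kobs–[I] regression), mean ± SD, nM. For the noncompetitive
#: modality established for this series, the true Ki equals Kiapp.
KIAPP_COMPOUND10_NM = 123.0
KIAPP_COMPOUND10_SD = 47.0

#: True Ki of compound 11 (nM), mean ± SD.
KI_COMPOUND11_NM = 45.0
KI_COMPOUND11_SD = 8.0

#: Apparent in vitro IC50s (μM) of the N-terminal truncation series of
#: compound 9 (1 hr preincubation, 10 μM substrate). Compound 15 was only
#: bounded (">1 mM"); it is stored as the censoring bound 1000 μM.
TRUNCATION_IC50_UM = {
    "9": 0.44,   # full-length Ac-RVRHA + phenylethyl tail
    "12": 0.55,  # P5 removed
    "13": 9.0,   # P5-P4 removed
    "14": 65.0,  # P5-P3 removed
    "15": 1000.0,  # P5-P2 removed; censored lower bound (> 1 mM)
}

#: Apparent IC50s (μM) from the covalent-reversible warhead screen on the
#: optimized Ac-RVRHA sequence (10 μM substrate, 1 hr preincubation).
WARHEAD_IC50_UM = {
    "boronate": 8.0,
    "ketoamide": 203.0,
}

#: Fold-changes quoted in the narrative of the truncation and warhead
#: screens (relative to compound 9 / between warheads).
QUOTED_FOLD_CHANGES = {
    "13_vs_9": 20.0,
    "14_vs_9": 150.0,
    "15_vs_9": 2250.0,
    "ketoamide_vs_boronate": 25.0,
}

#: Michaelis parameters of the fluorogenic transmembrane-peptide substrates
#: are not published; the synthetic world fixes plausible values for a slow
#: intramembrane protease acting on a micelle-solubilized peptide.
DEFAULT_KM_UM = 10.0
DEFAULT_KCAT_MIN = 0.1


def compound_scheme(compound: str, modality: Modality | str = Modality.noncompetitive,
                    Km: float = DEFAULT_KM_UM, kcat: float = DEFAULT_KCAT_MIN,
                    use_kiapp: bool = False) -> KineticScheme:
    """Build the one-step scheme for a characterized compound.

    ``use_kiapp=True`` (compound 10 only) uses the progress-curve-derived
    apparent constant (123 nM) instead of the rounded table value (120 nM);
    the two are equivalent for the noncompetitive modality.
    """
    c = COMPOUND_CONSTANTS[str(compound)]
    Ki = KIAPP_COMPOUND10_NM if (use_kiapp and str(compound) == "10") else c["Ki_nM"]
    return KineticScheme(modality=Modality(modality), Ki=Ki, koff=c["koff"],
                         Km=Km, kcat=kcat)
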