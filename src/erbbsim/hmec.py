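"""A compact reconstruction of the ErbB signalling core of a human
mammary epithelial cell (hMEC).

This is a self-contained ~52-node logical network capturing the
mechanisms needed for the bundled experiments: the ErbB dimerization
hierarchy (ErbB2-ErbB3 > EGFR-ErbB2 > EGFR-EGFR when partners are
expressed), ligand-specific EGFR endocytic trafficking (plasma membrane
-> clathrin-coated pit -> clathrin-coated vesicle -> early endosome ->
multivesicular body -> lysosome for EGF; recycling-biased, lysosome-free
transit for TGFa), downstream MAPK/PI3K arms, integrin signalling, a
GPCR/adenylyl-cyclase arm, and token stress inputs.

Mechanistic choices worth knowing:

* The EGF-bound EGFR homodimer internalizes through cCbl engagement
  (two consecutive active steps at the membrane), while active Src
  drives an additional, ligand-independent internalization route for
  the surface receptor.  Constitutive Src therefore keeps the receptor
  cycling through endocytic compartments even at very low EGF — the
  model's testable prediction about Src overexpression (surface
  receptor falls, compartment occupancy rises, with or without added
  ligand).
* Heterodimers do not enter the trafficking chain (ErbB2-containing
  dimers are endocytosis-impaired), so the chain tracks the homodimer
  exclusively.
* ErbB2 availability is expression minus degradation
  (``ErbB2_Contr AND NOT ErbB2Deg_Contr``).
* Src activation is receptor-driven here (homodimer or EGFR-ErbB2); the
  integrin route to Src is deliberately not wired in this reduction.
* ``ExtPump`` is accepted as an input for scenario compatibility but is
  not wired to any rule.
"""

from __future__ import annotations

from .logic import LogicalNetwork, extract_subnetwork

__all__ = ["HMEC_RULES", "build_hmec_mini", "trafficking_subchain",
           "TRAFFICKING_NODES"]

#: Canonical rule file.  Identifiers never assigned are external inputs;
#: the `# @external:` directive declares inputs referenced by no rule.
HMEC_RULES = """\
# hMEC ErbB core reconstruction (Boolean rules, plain rule-text format)
# @external: ExtPump

# Receptor expression
EGFR             = EGFR_Contr
ErbB2            = ErbB2_Contr AND NOT ErbB2Deg_Contr
ErbB3            = ErbB3_Contr

# Dimerization hierarchy (heterodimers outcompete the homodimer)
EGFR_EGFR_PM_EGF = EGFR AND EGF AND NOT ErbB2 AND NOT (CCP_E OR CCV_E OR EE_E OR MVB_E)
EGFR_PM_TGFa     = EGFR AND TGFa AND NOT ErbB2 AND NOT (CCP_T OR CCV_T OR EE_T)
EGFR_ErbB2       = EGFR AND (EGF OR TGFa) AND ErbB2 AND NOT ErbB3
ErbB2_ErbB3      = EGFR AND (EGF OR TGFa) AND ErbB2 AND ErbB3

# EGF-bound homodimer endocytic traffic (degradative route)
cCbl_E           = EGFR_EGFR_PM_EGF
CCP_E            = (EGFR_EGFR_PM_EGF AND cCbl_E) OR (Src_active AND EGFR AND NOT ErbB2 AND NOT (CCV_E OR EE_E OR MVB_E))
CCV_E            = CCP_E
EE_E             = CCV_E
MVB_E            = EE_E
LYS_E            = MVB_E

# TGFa-bound receptor traffic (recycling route; no lysosomal node)
cCbl_T           = EGFR_PM_TGFa
CCP_T            = EGFR_PM_TGFa AND (Src_active OR cCbl_T)
CCV_T            = CCP_T
EE_T             = CCV_T

# Src and MAPK cascade
Src_active       = EGFR_EGFR_PM_EGF OR EGFR_ErbB2
SOS              = EGFR_EGFR_PM_EGF OR EGFR_ErbB2 OR ErbB2_ErbB3 OR FAK
Ras              = SOS
Raf              = Ras
MEK              = Raf
Erk              = MEK

# PI3K/Akt arm
PI3K             = EGFR_EGFR_PM_EGF OR ErbB2_ErbB3 OR Ras
PIP3             = PI3K
Akt              = PIP3

# Integrin signalling
Integrin         = ECM
FAK              = Integrin
Rac              = FAK OR PIP3
Cdc42            = FAK

# GPCR / adenylyl cyclase arm (Gi attenuates Gs)
Gs               = alpha_sL
Gi               = alpha_iL
AC               = Gs AND NOT Gi
cAMP             = AC
PKA              = cAMP

# Stress and remaining GPCR token sinks
JNK              = Stress OR IL1_TNF
RhoA             = alpha_1213L
PLCb             = alpha_qL
"""

#: EGF-route trafficking chain used for exact-oracle cross-checks.
TRAFFICKING_NODES = ("EGFR_EGFR_PM_EGF", "cCbl_E", "CCP_E", "CCV_E",
                     "EE_E", "MVB_E", "LYS_E")


def build_hmec_mini() -> LogicalNetwork:
    """Build the canonical hMEC reconstruction (14 external inputs, 38
    rule-governed nodes); deterministic."""
    from .io import parse_rules
    return parse_rules(HMEC_RULES)


def trafficking_subchain() -> LogicalNetwork:
    """The EGF-route endocytic chain as a standalone network.

    7 internal nodes with EGF, EGFR, ErbB2 and Src_active promoted to
    external boundary inputs — small enough for the exact engine oracle.
    """
    return extract_subnetwork(build_hmec_mini(), TRAFFICKING_NODES)
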