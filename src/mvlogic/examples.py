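"""Bundled example models.

The p53-Mdm2 DNA-damage network: the transcription factor p53 induces
DNA repair and the synthesis of its own inhibitor Mdm2; nuclear Mdm2
blocks p53 activity, while p53 inhibits the nuclear translocation of
cytoplasmic Mdm2, and DNA damage promotes nuclear Mdm2 degradation.
p53 and cytoplasmic Mdm2 are ternary components (levels 0..2); DNA
damage and nuclear Mdm2 are Boolean.  The model has a single stable
state, the resting state ``0011``, and transient p53-Mdm2 oscillations
during DNA repair.
"""
from .formats import parse_mnet
from .model import LogicalModel

P53_MDM2_MNET = """\
DNAdam <- DNAdam & !p53:2
p53:2 <- !Mdm2nuc
Mdm2cyt:1 <- !p53:2
Mdm2cyt:2 <- p53:2
Mdm2nuc <- Mdm2cyt:2 | (Mdm2cyt & !p53 & !DNAdam)
"""


def p53_mdm2() -> LogicalModel:
    """The four-component p53-Mdm2 DNA-damage response model."""
    return parse_mnet(P53_MDM2_MNET)
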