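"""Shared vocabulary: cell-cycle phases, FUCCI colour classes and fate labels.

The fate ontology covers the outcomes observed in pulsed-cisplatin
time-lapse experiments:

PROLIF       two or more divisions within the observation window
SINGLE_DIV   exactly one division, no terminal G1 arrest afterwards
G2_EXIT      prolonged S/G2 arrest resolved into a G1-like (red) state
             without mitosis
G1_ABM       G1 arrest, no division ("G1 arrest before mitosis")
G1_AAM       one division followed by terminal G1 arrest
             ("G1 arrest after mitosis")
DBM          death before any division
DAM          death after at least one division
SG2_ARREST   persistent S/G2 arrest (still green at the end of the window)
"""

FATE_LABELS = (
    "PROLIF",
    "SINGLE_DIV",
    "G2_EXIT",
    "G1_ABM",
    "G1_AAM",
    "DBM",
    "DAM",
    "SG2_ARREST",
)

#: Cell-cycle phase at the moment of drug exposure.
EXPOSURE_PHASES = ("G1", "G1/S", "earlyS", "lateS", "G2/M", "untreated")

#: Per-frame FUCCI colour classes. GAP is the brief colourless window after
#: anaphase before the G1 reporter accumulates; DEAD is absorbing.
PHASE_CALL_LABELS = ("G1", "G1/S", "S/G2/M", "GAP", "DEAD")

#: Sentinel for cells outside the reduced (top-k) colour set.
UNASSIGNED = -1

UNCLASSIFIABLE = "UNCLASSIFIABLE"
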