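"""Published reference data for the JAM-A / ZO-2 PDZ-2 complex.

The C-terminal 10-mer of human JAM-A (EFKQTSSFLV, ending in the canonical
PDZ-binding ...SFLV motif) docks into the second PDZ domain of ZO-2.  The
values below are the literature-reported residue-level characterisation of
that complex: per-residue PARCH hydropathy values of the peptide, the
COG-contact assignments at a 6.5 A cutoff, and the umbrella-sampling/WHAM
binding energy with the location of the free-energy minimum along the
intermolecular distance.  They serve as in-package inputs for summary
statistics and as the shape specification for the toy umbrella-sampling
reference dataset.
"""

from __future__ import annotations

# C-terminal 10-mer of human JAM-A, N->C order.
JAM_A_TAIL = "EFKQTSSFLV"

# ZO-2 PDZ-2 segment, residues 306-386 of UniProt Q9UDY2.
PDZ2_SEQUENCE = (
    "IGVLLMKSRANEEYGLRLGSQIFVKEMTRTGLATKDGNLHEGDIILKINGTVTENMSLTDARKLIEKSRGKLQLVVLRDSQ"
)
PDZ2_FIRST_INDEX = 306

# Reported PARCH hydropathy values of the peptide, keyed by backwards
# position (C-1 = C-terminal valine).  Scale 0-10; < 1 is hydrophobic.
JAM_A_PARCH = {
    "C-1": 0.9,
    "C-2": 0.4,
    "C-3": 0.1,
    "C-4": 0.2,
    "C-5": 0.0,
    "C-6": 0.2,
    "C-7": 0.1,
    "C-8": 1.3,
    "C-9": 0.3,
    "C-10": 2.2,
}

# Reported COG contacts (6.5 A cutoff) between peptide positions and
# PDZ-2 residues; empty set = no contact registered.
JAM_A_PDZ2_CONTACTS = {
    "C-1": frozenset({"L321", "L323", "I370", "R367"}),
    "C-2": frozenset({"R322"}),
    "C-3": frozenset({"G324", "L363", "R367"}),
    "C-4": frozenset({"R322", "K330", "E331"}),
    "C-5": frozenset(),
    "C-6": frozenset(),
    "C-7": frozenset({"G347", "S325", "K330"}),
    "C-8": frozenset(),
    "C-9": frozenset({"Q326", "F328"}),
    "C-10": frozenset({"G347"}),
}

# Reported binding energetics from umbrella sampling + WHAM on the
# all-atom complex: well depth of the PMF and location of its minimum
# along the intermolecular distance xi.
BINDING_ENERGY_KJ_MOL = -59.4
BINDING_ENERGY_ERROR_KJ_MOL = 1.75
PMF_MINIMUM_XI_NM = 0.9

# Simulation temperature of the underlying molecular-dynamics protocol.
TEMPERATURE_K = 310.15

# Umbrella-sampling protocol constants: harmonic force constant and
# window spacing along xi.
UMBRELLA_FORCE_CONSTANT = 800.0  # kJ/mol/nm^2
UMBRELLA_WINDOW_SPACING_NM = 0.05
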