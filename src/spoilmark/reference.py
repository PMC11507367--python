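"""Published reference values of the raw-milk storage study this package models.

The study stored raw milk for ten days at 4 degC, digested daily samples
in-solution and in-gel (SDS-PAGE bands), and selected trend features by
PLSR + VIP score.  Its printed result tables are small enough to carry as
constants; they serve as worked-example inputs for the cross-matching and
identification stages and as regression anchors in the test suite.

``load_milk_proteins`` returns the seven milk-protein sequences used as the
identification search space.  They are bundled for offline use; the
alpha-S1-casein entry (P02662) is the load-bearing one for the published
identifications and its C-terminal region is pinned by the published
peptide positions (PLW at precursor 212-214, FSDIPNPIGSENSEK at 194-208).
The other six entries are transcribed canonical precursor sequences that
act as search-space background; refresh them from UniProt when exactness
matters beyond that role.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .digestion import ProteinRecord, read_fasta

#: Accession of bovine alpha-S1-casein, the protein behind all three
#: published peptide identifications.
CASEIN_ALPHA_S1 = "P02662"

#: Top-10 trend features of the in-solution PLSR, ranked by VIP score.
#: "trend" is I (intensity increases with storage day) or D (decreases);
#: "sds_band"/"sds_partner" give the in-gel partner feature when one was
#: found at the cross-match tolerances (0.01 Th, 5 s).
TOP10_FEATURES = pd.DataFrame(
    [
        ("FT 196375", 322.9788, 230.3010, 1, 1.6993, "I", None, None),
        ("FT 113694", 399.6896, 587.1291, 2, 1.6491, "D", "8", "sdsFT20628"),
        ("FT 152646", 472.1981, 614.6866, 2, 1.6319, "D", None, None),
        ("FT 100975", 376.1899, 587.4633, 2, 1.6277, "D", "8", "sdsFT4082"),
        ("FT 10104", 415.1563, 614.5459, 2, 1.6210, "D", None, None),
        ("FT 221952", 620.3291, 403.8281, 2, 1.6129, "I", None, None),
        ("FT 34290", 442.1821, 320.1580, 2, 1.5732, "D", "8", "sdsFT1284"),
        ("FT 69089", 594.6089, 543.7169, 3, 1.5687, "D", None, None),
        ("FT 90590", 502.1869, 577.8206, 1, 1.5678, "D", None, None),
        ("FT 53501", 411.0683, 278.2279, 1, 1.5637, "I", None, None),
    ],
    columns=["feature_id", "mz", "rt", "charge", "vip", "trend",
             "sds_band", "sds_partner"],
)

#: The three features identified as alpha-S1-casein peptides, with the
#: assigned sequence, modification and 1-based precursor positions.
IDENTIFIED_FEATURES = pd.DataFrame(
    [
        ("FT 128885", 415.2385, 538.6355, 1, "D", None, "PLW",
         CASEIN_ALPHA_S1, 212, 214),
        ("FT 62883", 857.3572, 465.8155, 2, "D", "phosphorylation",
         "FSDIPNPIGSENSEK", CASEIN_ALPHA_S1, 194, 208),
        ("FT 298105", 571.9066, 465.9806, 3, "D", "phosphorylation",
         "FSDIPNPIGSENSEK", CASEIN_ALPHA_S1, 194, 208),
    ],
    columns=["feature_id", "mz", "rt", "charge", "trend", "modification",
             "sequence", "protein", "start", "end"],
)

#: Neutral-mass difference (Da) between FT 113694 and FT 100975, the pair of
#: co-eluting band-8 features interpreted as sharing a peptide origin.
NEUTRAL_MASS_DIFFERENCE = 46.9994


def load_milk_proteins() -> list[ProteinRecord]:
    """The seven bundled milk-protein sequences (see module docstring)."""
    ref = resources.files("spoilmark").joinpath("data/milk_proteins.fasta")
    with resources.as_file(ref) as path:
        return read_fasta(path)
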