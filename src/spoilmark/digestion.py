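"""In-silico proteolysis, variable modifications and mass-tolerance matching.

The identification step of the milk-spoilage workflow compares the neutral
monoisotopic mass of each selected LC-MS feature (computed from its m/z and
charge) against a database of theoretical peptides built from the major milk
proteins.  The database combines two cleavage regimes:

* **Tryptic** peptides: cleavage C-terminal to K/R (optionally suppressed
  before proline), up to a configurable number of missed cleavages.
* **Endogenous-protease** peptides: raw milk carries active proteases
  (plasmin, cathepsins B/D, elastase) whose collective specificity is
  approximated by additional cleavage adjacent to the hydrophobic / small
  residues A, V, L, I, P, M, F, W, G, Q, T.  Because cathepsin-D-type
  specificity is described by both the P1 and the P1' position, a peptide
  terminus may sit on either side of a listed residue.  These cleavages are
  sporadic in vivo, so uncut extended sites are not counted against the
  missed-cleavage budget (which applies to K/R sites only); instead the
  enumeration is bounded by a peptide-length cap.

Variable modifications are applied as single placements by default; each of
the ten spoilage-relevant modification chemistries carries its canonical
monoisotopic mass delta and a residue-site rule.
"""

from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .exceptions import ConfigurationError, ParseError
from .features import PROTON_MASS, Feature, neutral_mass

logger = logging.getLogger(__name__)

#: Monoisotopic residue (amino-acid minus water) masses in Da,
#: standard community values.
RESIDUE_MASS = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047679, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}

#: Monoisotopic mass of water in Da (peptide = sum of residues + water).
WATER_MASS = 18.010565

VALID_RESIDUES = frozenset(RESIDUE_MASS)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence in precursor (signal-peptide-included) numbering."""

    accession: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"{self.accession}: empty sequence")
        for i, ch in enumerate(self.sequence):
            if ch not in VALID_RESIDUES:
                raise ParseError(
                    f"{self.accession}: illegal residue {ch!r} at position {i + 1}")


@dataclass(frozen=True)
class CleavageRules:
    """Combined tryptic + endogenous-protease cleavage specification.

    ``max_missed_cleavages`` counts internal *tryptic* (K/R) sites only.
    ``extended_before`` additionally allows a terminus N-terminal to an
    extended-site residue (P1' specificity); without it the extended rule is
    purely C-terminal like the tryptic one.
    """

    primary_sites: frozenset[str] = frozenset("KR")
    extended_sites: frozenset[str] = frozenset("AVLIPMFWGQT")
    max_missed_cleavages: int = 2
    proline_rule: bool = True
    extended_before: bool = True
    min_length_tryptic: int = 1
    min_length_extended: int = 3
    max_length_extended: int = 30

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ConfigurationError("max_missed_cleavages must be >= 0")
        bad = (self.primary_sites | self.extended_sites) - VALID_RESIDUES
        if bad:
            raise ConfigurationError(f"illegal cleavage-site symbols: {sorted(bad)}")
        if self.min_length_tryptic < 1 or self.min_length_extended < 1:
            raise ConfigurationError("minimum peptide lengths must be >= 1")
        if self.max_length_extended < self.min_length_extended:
            raise ConfigurationError("max_length_extended < min_length_extended")


@dataclass(frozen=True)
class Modification:
    """A variable modification: name, monoisotopic delta, allowed sites.

    ``sites`` is a set of residue letters, optionally including the pseudo
    site ``"nterm"`` (peptide N-terminus, placed at residue index 0).
    """

    name: str
    delta: float
    sites: frozenset[str]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ConfigurationError(f"modification {self.name!r} has no allowed sites")


@dataclass(frozen=True)
class ModificationSet:
    modifications: tuple[Modification, ...] = ()
    max_mods_per_peptide: int = 1


def default_modifications(max_mods_per_peptide: int = 1) -> ModificationSet:
    """The ten variable modifications considered for spoiling raw milk.

    Deltas are the canonical monoisotopic values; site rules reflect the
    dominant chemistry (Maillard adducts on lysine, oxidation on M/W,
    phosphorylation on S/T/Y, ...).  Acetylation is restricted to lysine by
    default; add the pseudo-site ``"nterm"`` to model N-terminal acetylation
    (it would otherwise generate a variant of every single peptide).
    """
    mk = Modification
    return ModificationSet(modifications=(
        mk("acetylation", 42.010565, frozenset("K")),
        mk("carbamidomethylation", 57.021464, frozenset("C")),
        mk("carboxyethylation", 72.021129, frozenset("K")),
        mk("carboxymethylation", 58.005479, frozenset("K")),
        mk("hexosylation", 162.052824, frozenset("K")),
        mk("hydroxylation", 15.994915, frozenset("P")),
        mk("lactosylation", 324.105647, frozenset("K")),
        mk("methylation", 14.015650, frozenset({"K", "R"})),
        mk("oxidation", 15.994915, frozenset({"M", "W"})),
        mk("phosphorylation", 79.966331, frozenset({"S", "T", "Y"})),
    ), max_mods_per_peptide=max_mods_per_peptide)


@dataclass(frozen=True)
class TheoreticalPeptide:
    """A candidate peptide with 1-based inclusive precursor positions."""

    sequence: str
    protein: str
    start: int
    end: int
    missed_cleavages: int
    modifications: tuple[tuple[str, int], ...]  # (name, 1-based site in peptide; 0 = N-term)
    neutral_mass: float

    @property
    def is_modified(self) -> bool:
        return bool(self.modifications)


@dataclass(frozen=True)
class MatchResult:
    """A feature / theoretical-peptide pair within the mass tolerance."""

    feature_id: str
    peptide: TheoreticalPeptide
    charge: int
    observed_neutral_mass: float
    relative_deviation: float   # (observed - theoretical) / theoretical


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse protein records from a FASTA file (UniProt-style headers supported)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = re.sub(r"\s+", "", str(rec.seq)).upper()
        m = re.match(r"^(?:sp|tr)\|([^|]+)\|(\S+)", rec.description)
        accession = m.group(1) if m else rec.id
        name = m.group(2) if m else rec.description
        records.append(ProteinRecord(accession=accession, name=name, sequence=seq))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def _tryptic_cuts(seq: str, rules: CleavageRules) -> list[int]:
    """0-based cut positions (between seq[i-1] and seq[i]) from the K/R rule."""
    cuts = []
    for i in range(1, len(seq)):
        if seq[i - 1] in rules.primary_sites:
            if rules.proline_rule and seq[i] == "P":
                continue
            cuts.append(i)
    return cuts


def _extended_cuts(seq: str, rules: CleavageRules) -> set[int]:
    cuts: set[int] = set()
    for i in range(1, len(seq)):
        if seq[i - 1] in rules.extended_sites:
            cuts.add(i)
        if rules.extended_before and seq[i] in rules.extended_sites:
            cuts.add(i)
    return cuts


def digest(protein: ProteinRecord, rules: CleavageRules | None = None) -> list[TheoreticalPeptide]:
    """Enumerate theoretical peptides of a protein under the combined rules.

    The output is the union of (i) fully tryptic peptides with at most
    ``max_missed_cleavages`` internal K/R sites and (ii) peptides with at
    least one extended-site terminus, the same internal-tryptic budget and
    length within ``[min_length_extended, max_length_extended]``.  Each span
    appears once; peptides are ordered by position.
    """
    if rules is None:
        rules = CleavageRules()
    seq = protein.sequence
    n = len(seq)
    tryptic = _tryptic_cuts(seq, rules)
    tryptic_set = set(tryptic)
    tryptic_bounds = [0] + tryptic + [n]
    # prefix[i] = number of tryptic cut positions <= i
    prefix = [0] * (n + 1)
    for i in range(1, n + 1):
        prefix[i] = prefix[i - 1] + (1 if i in tryptic_set else 0)

    def internal_tryptic(start: int, end: int) -> int:
        # cut positions strictly inside (start, end)
        cnt = prefix[end - 1] - prefix[start]
        return cnt

    spans: dict[tuple[int, int], int] = {}

    # (i) fully tryptic peptides
    for ai, start in enumerate(tryptic_bounds[:-1]):
        for end in tryptic_bounds[ai + 1:]:
            if internal_tryptic(start, end) > rules.max_missed_cleavages:
                break
            if end - start >= rules.min_length_tryptic:
                spans[(start, end)] = internal_tryptic(start, end)

    # (ii) extended-site peptides
    ext = _extended_cuts(seq, rules)
    all_bounds = sorted(set(tryptic_bounds) | ext)
    bound_set = set(all_bounds)
    for start in all_bounds:
        lo, hi = start + rules.min_length_extended, min(n, start + rules.max_length_extended)
        for end in range(lo, hi + 1):
            if end not in bound_set or (start, end) in spans:
                continue
            if internal_tryptic(start, end) <= rules.max_missed_cleavages:
                spans[(start, end)] = internal_tryptic(start, end)

    peptides = []
    for (start, end) in sorted(spans):
        pep_seq = seq[start:end]
        peptides.append(TheoreticalPeptide(
            sequence=pep_seq, protein=protein.accession,
            start=start + 1, end=end,
            missed_cleavages=spans[(start, end)],
            modifications=(),
            neutral_mass=peptide_neutral_mass(pep_seq)))
    return peptides


def digest_all(proteins: Iterable[ProteinRecord],
               rules: CleavageRules | None = None) -> list[TheoreticalPeptide]:
    """Digest several proteins into one peptide list."""
    out: list[TheoreticalPeptide] = []
    for protein in proteins:
        out.extend(digest(protein, rules))
    if not out:
        raise ConfigurationError("digestion produced no peptides")
    return out


# ---------------------------------------------------------------------------
# Modifications and masses
# ---------------------------------------------------------------------------

def peptide_neutral_mass(sequence: str,
                         modifications: Sequence[Modification] | Sequence[float] = ()) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas."""
    try:
        mass = sum(RESIDUE_MASS[ch] for ch in sequence) + WATER_MASS
    except KeyError as exc:
        raise ConfigurationError(f"illegal residue {exc.args[0]!r} in {sequence!r}") from None
    for mod in modifications:
        mass += mod.delta if isinstance(mod, Modification) else float(mod)
    return mass


def theoretical_mz(neutral: float, charge: int) -> float:
    """m/z of the [M + zH]^z+ ion: ``(M + z * m_proton) / z``."""
    if charge < 1:
        raise ConfigurationError(f"charge must be >= 1, got {charge}")
    return (neutral + charge * PROTON_MASS) / charge


def apply_modifications(peptide: TheoreticalPeptide,
                        mods: ModificationSet) -> list[TheoreticalPeptide]:
    """The unmodified peptide plus every allowed modification placement.

    With ``max_mods_per_peptide = 1`` (the default) each variant carries one
    modification at one allowed site; distinct sites of the same chemistry
    yield distinct (isobaric) variants.  Placements are recorded as
    ``(name, site)`` with the 1-based residue position within the peptide
    (0 denotes the peptide N-terminus).
    """
    variants = [peptide]
    if mods.max_mods_per_peptide < 1:
        return variants
    placements: list[tuple[str, int, float]] = []
    for mod in mods.modifications:
        if "nterm" in mod.sites:
            placements.append((mod.name, 0, mod.delta))
        for i, ch in enumerate(peptide.sequence):
            if ch in mod.sites:
                placements.append((mod.name, i + 1, mod.delta))
    import itertools

    for r in range(1, mods.max_mods_per_peptide + 1):
        for combo in itertools.combinations(placements, r):
            sites = [c[1] for c in combo]
            if len(set(sites)) < len(sites):
                continue  # one modification per site
            delta = sum(c[2] for c in combo)
            variants.append(replace(
                peptide,
                modifications=tuple(sorted((c[0], c[1]) for c in combo)),
                neutral_mass=peptide.neutral_mass + delta))
    return variants


def build_database(proteins: Iterable[ProteinRecord],
                   rules: CleavageRules | None = None,
                   mods: ModificationSet | None = None) -> list[TheoreticalPeptide]:
    """Digest, then expand every peptide with its modification variants."""
    if mods is None:
        mods = default_modifications()
    out: list[TheoreticalPeptide] = []
    for pep in digest_all(proteins, rules):
        out.extend(apply_modifications(pep, mods))
    return out


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_features(features: Sequence[Feature], peptides: Sequence[TheoreticalPeptide],
                   rel_tol: float = 2e-5) -> list[MatchResult]:
    """Match observed features to theoretical peptides by neutral mass.

    For each feature with a determined charge the observed neutral mass is
    ``(m/z - m_proton) * z``; every peptide whose theoretical mass deviates
    by at most ``rel_tol`` (relative, default 0.002%) is reported, sorted by
    absolute deviation within each feature.  Features with charge 0 are
    skipped with a warning.
    """
    if rel_tol < 0:
        raise ConfigurationError(f"rel_tol must be >= 0, got {rel_tol}")
    if not peptides:
        raise ConfigurationError("empty theoretical peptide list")
    order = sorted(range(len(peptides)), key=lambda i: peptides[i].neutral_mass)
    masses = [peptides[i].neutral_mass for i in order]
    results: list[MatchResult] = []
    for feat in features:
        if feat.charge < 1:
            logger.warning("feature %s has undetermined charge; skipped in identification",
                           feat.id)
            continue
        obs = neutral_mass(feat.mz, feat.charge)
        lo = bisect.bisect_left(masses, obs / (1 + rel_tol))
        hi = bisect.bisect_right(masses, obs / (1 - rel_tol) if rel_tol < 1 else float("inf"))
        hits = []
        for j in range(lo, hi):
            pep = peptides[order[j]]
            dev = (obs - pep.neutral_mass) / pep.neutral_mass
            if abs(dev) <= rel_tol:
                hits.append(MatchResult(
                    feature_id=feat.id, peptide=pep, charge=feat.charge,
                    observed_neutral_mass=obs, relative_deviation=dev))
        hits.sort(key=lambda m: (abs(m.relative_deviation), m.peptide.protein,
                                 m.peptide.start, m.peptide.modifications))
        results.extend(hits)
    return results
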