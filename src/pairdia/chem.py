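"""Peptide mass arithmetic, stable-isotope labels, digestion and variant panels.

Everything downstream of acquisition design rests on a small amount of
peptide chemistry: monoisotopic masses, precursor m/z at a given charge,
b/y fragment series, and the behaviour of C-terminal stable-isotope labels
(heavy Lys: six 13C + two 15N; heavy Glu: five 13C + one 15N).  A C-terminal
label shifts every y ion but no b ion, which is exactly why coisolating a
light/heavy pair in one isolation window destroys the b series for
quantification while separating the pair preserves it.

All masses are monoisotopic.  Residue masses come from the standard
amino-acid table (:mod:`pyteomics.mass`); label shifts are computed from the
13C-12C and 15N-14N isotope mass differences rather than typed in.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from pyteomics import mass as _pmass
from pyteomics import parser as _pparser

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "HEAVY_K_SHIFT",
    "HEAVY_E_SHIFT",
    "METHYLTHIO_C",
    "CANONICAL_RESIDUES",
    "AminoAcidTable",
    "LabelKind",
    "IsotopeLabel",
    "LabeledPeptide",
    "PrecursorIon",
    "FragmentIon",
    "FragmentPartition",
    "IsotopePair",
    "Protease",
    "Variant",
    "PanelCandidate",
    "PanelResult",
    "get_protease",
    "peptide_monoisotopic_mass",
    "precursor_mz",
    "precursor_ion",
    "make_pair",
    "fragment_series",
    "classify_pair_fragments",
    "digest",
    "apply_variant",
    "variant_panel",
]

PROTON_MASS = 1.00727646688
WATER_MASS = _pmass.calculate_mass(formula="H2O")  # 18.0105647 Da

_C13 = _pmass.nist_mass["C"][13][0] - _pmass.nist_mass["C"][12][0]
_N15 = _pmass.nist_mass["N"][15][0] - _pmass.nist_mass["N"][14][0]

#: Mass shift of a 13C6 15N2 lysine relative to light lysine (Da).
HEAVY_K_SHIFT = 6 * _C13 + 2 * _N15  # 8.014199
#: Mass shift of a 13C5 15N1 glutamic acid relative to light Glu (Da).
HEAVY_E_SHIFT = 5 * _C13 + 1 * _N15  # 6.013809

#: Methylthio (MMTS) fixed modification on cysteine (Da).
METHYLTHIO_C = 45.98772

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class AminoAcidTable:
    """Monoisotopic residue masses plus the constants of peptide arithmetic.

    ``fixed_mods`` maps a residue letter to a mass shift applied to every
    occurrence (e.g. methylthio on Cys for MMTS-alkylated samples).  The
    default table carries no fixed modifications.
    """

    residue_masses: dict[str, float] = field(
        default_factory=lambda: {
            aa: _pmass.std_aa_mass[aa] for aa in sorted(CANONICAL_RESIDUES)
        }
    )
    water_mass: float = WATER_MASS
    proton_mass: float = PROTON_MASS
    fixed_mods: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = CANONICAL_RESIDUES - set(self.residue_masses)
        if missing:
            raise ValueError(f"residue mass table incomplete: missing {sorted(missing)}")
        if any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("residue masses must be positive")

    def residue_mass(self, aa: str) -> float:
        return self.residue_masses[aa] + self.fixed_mods.get(aa, 0.0)

    def with_methylthio_cys(self) -> "AminoAcidTable":
        mods = dict(self.fixed_mods)
        mods["C"] = mods.get("C", 0.0) + METHYLTHIO_C
        return replace(self, fixed_mods=mods)


DEFAULT_TABLE = AminoAcidTable()


class LabelKind(str, enum.Enum):
    NONE = "none"
    HEAVY_K = "heavy_K"
    HEAVY_E = "heavy_E"


_LABEL_SHIFT = {
    LabelKind.NONE: 0.0,
    LabelKind.HEAVY_K: HEAVY_K_SHIFT,
    LabelKind.HEAVY_E: HEAVY_E_SHIFT,
}
_LABEL_RESIDUE = {LabelKind.HEAVY_K: "K", LabelKind.HEAVY_E: "E"}


@dataclass(frozen=True)
class IsotopeLabel:
    """A stable-isotope label on one residue of a peptide.

    ``labeled_position`` is the 0-based index of the labelled residue within
    the peptide; for the two heavy kinds used here it is the C-terminal
    residue.  ``kind=NONE`` denotes the light channel.
    """

    kind: LabelKind = LabelKind.NONE
    labeled_position: int | None = None

    @property
    def mass_shift(self) -> float:
        return _LABEL_SHIFT[self.kind]

    @classmethod
    def none(cls) -> "IsotopeLabel":
        return cls(LabelKind.NONE, None)

    @classmethod
    def c_terminal(cls, kind: LabelKind | str, sequence: str) -> "IsotopeLabel":
        """Label the C-terminal residue of ``sequence`` with ``kind``.

        Raises if the terminal residue does not match the label chemistry
        (heavy Lys requires K, heavy Glu requires E).
        """
        kind = LabelKind(kind)
        if kind is LabelKind.NONE:
            return cls.none()
        expected = _LABEL_RESIDUE[kind]
        if not sequence or sequence[-1] != expected:
            raise ValueError(
                f"{kind.value} label requires C-terminal {expected!r}, "
                f"got {sequence[-1:]!r}"
            )
        return cls(kind, len(sequence) - 1)


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("peptide sequence is empty")
    for i, aa in enumerate(sequence):
        if aa not in CANONICAL_RESIDUES:
            raise ValueError(
                f"non-canonical residue {aa!r} at position {i + 1} in {sequence!r}"
            )


@dataclass(frozen=True)
class LabeledPeptide:
    """A peptide with an optional isotope label and parent-protein coordinates.

    ``start``/``end`` are 1-based inclusive coordinates in the parent protein
    (optional for free-floating peptides).
    """

    sequence: str
    label: IsotopeLabel = field(default_factory=IsotopeLabel.none)
    protein_id: str | None = None
    start: int | None = None
    end: int | None = None
    protease: str | None = None

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        n = len(self.sequence)
        if (self.start is None) != (self.end is None):
            raise ValueError("start and end must be given together")
        if self.start is not None:
            if not 1 <= self.start <= self.end:
                raise ValueError(f"invalid coordinates {self.start}-{self.end}")
            if self.end - self.start + 1 != n:
                raise ValueError(
                    f"coordinates {self.start}-{self.end} do not match "
                    f"length {n} of {self.sequence!r}"
                )
        pos = self.label.labeled_position
        if pos is not None:
            if not 0 <= pos < n:
                raise ValueError(f"label position {pos} outside peptide of length {n}")
            expected = _LABEL_RESIDUE.get(self.label.kind)
            if expected is not None and self.sequence[pos] != expected:
                raise ValueError(
                    f"label {self.label.kind.value} on residue "
                    f"{self.sequence[pos]!r} (expects {expected!r})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_heavy(self) -> bool:
        return self.label.kind is not LabelKind.NONE

    def with_label(self, kind: LabelKind | str) -> "LabeledPeptide":
        return replace(self, label=IsotopeLabel.c_terminal(kind, self.sequence))


def peptide_monoisotopic_mass(
    peptide: LabeledPeptide | str, table: AminoAcidTable = DEFAULT_TABLE
) -> float:
    """Neutral monoisotopic mass of a (possibly labelled) peptide in Da."""
    if isinstance(peptide, str):
        peptide = LabeledPeptide(peptide)
    total = sum(table.residue_mass(aa) for aa in peptide.sequence)
    return total + table.water_mass + peptide.label.mass_shift


def precursor_mz(
    peptide: LabeledPeptide | str,
    charge: int,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> float:
    """m/z of the [M + zH]^z+ precursor.  Full precision; round for display."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    mass = peptide_monoisotopic_mass(peptide, table)
    return (mass + charge * table.proton_mass) / charge


@dataclass(frozen=True)
class PrecursorIon:
    peptide: LabeledPeptide
    charge: int
    mz: float


def precursor_ion(
    peptide: LabeledPeptide | str, charge: int, table: AminoAcidTable = DEFAULT_TABLE
) -> PrecursorIon:
    if isinstance(peptide, str):
        peptide = LabeledPeptide(peptide)
    return PrecursorIon(peptide, charge, precursor_mz(peptide, charge, table))


@dataclass(frozen=True)
class IsotopePair:
    """A light precursor and its heavy-labelled twin at the same charge."""

    light: PrecursorIon
    heavy: PrecursorIon

    def __post_init__(self) -> None:
        if self.light.peptide.sequence != self.heavy.peptide.sequence:
            raise ValueError("light and heavy peptides must share a sequence")
        if self.light.charge != self.heavy.charge:
            raise ValueError("light and heavy precursors must share a charge")
        if self.heavy.peptide.label.kind is LabelKind.NONE:
            raise ValueError("heavy channel carries no label")

    @property
    def charge(self) -> int:
        return self.light.charge

    @property
    def sequence(self) -> str:
        return self.light.peptide.sequence

    @property
    def mz_spacing(self) -> float:
        """heavy m/z minus light m/z; equals label shift / charge."""
        return self.heavy.mz - self.light.mz


def make_pair(
    sequence: str,
    charge: int,
    label_kind: LabelKind | str = LabelKind.HEAVY_K,
    table: AminoAcidTable = DEFAULT_TABLE,
    **peptide_kw,
) -> IsotopePair:
    """Build a light/heavy precursor pair for ``sequence`` at ``charge``."""
    light_pep = LabeledPeptide(sequence, **peptide_kw)
    heavy_pep = light_pep.with_label(label_kind)
    return IsotopePair(
        precursor_ion(light_pep, charge, table),
        precursor_ion(heavy_pep, charge, table),
    )


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'b' or 'y'
    index: int  # 1 .. n-1
    charge: int
    mz: float
    carries_label: bool

    @property
    def name(self) -> str:
        return f"{self.series}{self.index}"


def fragment_series(
    peptide: LabeledPeptide | str,
    fragment_charge: int = 1,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> list[FragmentIon]:
    """Singly-resolved b and y series: b1..b(n-1) then y1..y(n-1).

    A fragment carries the label iff its residue span contains the labelled
    position, so C-terminal labels shift every y ion and no b ion.  The
    series obey the complementarity identity
    ``b_i + y_(n-i) = neutral mass + 2*proton`` (per unit fragment charge).
    """
    if isinstance(peptide, str):
        peptide = LabeledPeptide(peptide)
    if fragment_charge < 1:
        raise ValueError("fragment charge must be >= 1")
    seq = peptide.sequence
    n = len(seq)
    if n < 2:
        raise ValueError("fragments require a peptide of length >= 2")
    pos = peptide.label.labeled_position
    shift = peptide.label.mass_shift
    z = fragment_charge
    out: list[FragmentIon] = []
    prefix = 0.0
    for i in range(1, n):
        prefix += table.residue_mass(seq[i - 1])
        labelled = pos is not None and pos < i
        m = prefix + (shift if labelled else 0.0)
        out.append(FragmentIon("b", i, z, (m + z * table.proton_mass) / z, labelled))
    suffix = 0.0
    for j in range(1, n):
        suffix += table.residue_mass(seq[n - j])
        labelled = pos is not None and pos >= n - j
        m = suffix + table.water_mass + (shift if labelled else 0.0)
        out.append(FragmentIon("y", j, z, (m + z * table.proton_mass) / z, labelled))
    return out


@dataclass(frozen=True)
class FragmentPartition:
    """Partition of a pair's fragments into shared and channel-unique ions."""

    shared: tuple[FragmentIon, ...]
    unique_light: tuple[FragmentIon, ...]
    unique_heavy: tuple[FragmentIon, ...]
    quantifiable_count_light: int


def classify_pair_fragments(
    pair: IsotopePair,
    coisolated: bool,
    mz_tolerance: float = 0.01,
    observed: set[str] | None = None,
    fragment_charge: int = 1,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> FragmentPartition:
    """Which fragments of a light/heavy pair can be quantified independently.

    Under coisolation (both precursors in one isolation window) a fragment is
    *shared* iff its light and heavy m/z agree within ``mz_tolerance`` — for
    C-terminal labels that is the whole b series — and only channel-unique
    ions are quantifiable.  When the pair is isolated in separate windows,
    every fragment of each channel is quantifiable.  ``observed`` optionally
    restricts counting to a set of ion names (e.g. ``{"b3", "y4"}``) actually
    detected in a run.
    """
    frags_l = fragment_series(pair.light.peptide, fragment_charge, table)
    frags_h = fragment_series(pair.heavy.peptide, fragment_charge, table)

    def keep(f: FragmentIon) -> bool:
        return observed is None or f.name in observed

    shared: list[FragmentIon] = []
    unique_l: list[FragmentIon] = []
    unique_h: list[FragmentIon] = []
    if coisolated:
        for fl, fh in zip(frags_l, frags_h):
            if abs(fl.mz - fh.mz) <= mz_tolerance:
                shared.append(fl)
            else:
                unique_l.append(fl)
                unique_h.append(fh)
        count = sum(1 for f in unique_l if keep(f))
    else:
        unique_l = list(frags_l)
        unique_h = list(frags_h)
        count = sum(1 for f in unique_l if keep(f))
    return FragmentPartition(tuple(shared), tuple(unique_l), tuple(unique_h), count)


# ---------------------------------------------------------------------------
# Proteolytic digestion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Protease:
    """Cleavage specificity, expressed as a lookahead/lookbehind regex rule."""

    name: str
    cleave_after: frozenset[str]
    rule: str  # regex understood by pyteomics.parser


PROTEASES: dict[str, Protease] = {
    # Trypsin/P: cleaves after K or R including before proline (the
    # specificity used by most modern search engines).
    "trypsin_p": Protease("trypsin_p", frozenset("KR"), r"(?<=[KR])"),
    # Classical trypsin: no cleavage when proline follows.
    "trypsin": Protease("trypsin", frozenset("KR"), r"(?<=[KR])(?!P)"),
    "lysc": Protease("lysc", frozenset("K"), r"(?<=K)"),
    # GluC in bicarbonate-style buffers: Glu-specific.
    "gluc": Protease("gluc", frozenset("E"), r"(?<=E)"),
    # GluC in phosphate buffers also cleaves after Asp.
    "gluc_de": Protease("gluc_de", frozenset("ED"), r"(?<=[ED])"),
}


def get_protease(name: str | Protease) -> Protease:
    if isinstance(name, Protease):
        return name
    try:
        return PROTEASES[name]
    except KeyError:
        raise ValueError(
            f"unknown protease {name!r}; known: {sorted(PROTEASES)}"
        ) from None


def digest(
    protein: str,
    protease: str | Protease,
    max_missed_cleavages: int = 0,
    protein_id: str | None = None,
) -> list[LabeledPeptide]:
    """In-silico digest with 1-based inclusive coordinates.

    At 0 missed cleavages the returned peptides partition the protein; with
    ``k`` allowed missed cleavages every concatenation of up to ``k + 1``
    adjacent fragments is also emitted.  Results are ordered by start then
    length.
    """
    if not protein:
        raise ValueError("protein sequence is empty")
    _check_sequence(protein)
    prot = get_protease(protease)
    pieces = sorted(
        _pparser.icleave(protein, prot.rule, missed_cleavages=max_missed_cleavages),
        key=lambda sp: (sp[0], len(sp[1])),
    )
    return [
        LabeledPeptide(
            seq,
            protein_id=protein_id,
            start=start0 + 1,
            end=start0 + len(seq),
            protease=prot.name,
        )
        for start0, seq in pieces
    ]


# ---------------------------------------------------------------------------
# Variant panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    """A protein-level variant: single substitution or contiguous deletion.

    Coordinates are 1-based in the wild-type protein.  For substitutions
    ``position``/``ref``/``alt`` are used; for deletions ``position`` .. ``end``
    is the removed span.
    """

    kind: str  # 'sub' | 'del'
    position: int
    ref: str | None = None
    alt: str | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("sub", "del"):
            raise ValueError(f"variant kind must be 'sub' or 'del', got {self.kind!r}")
        if self.kind == "sub" and (self.ref is None or self.alt is None):
            raise ValueError("substitution requires ref and alt residues")

    @property
    def name(self) -> str:
        if self.kind == "sub":
            return f"{self.ref}{self.position}{self.alt}"
        return f"del{self.position}-{self.end}"


def apply_variant(protein_wt: str, variant: Variant) -> tuple[str, tuple[int, int]]:
    """Mutant sequence plus the variant site span in *mutant* coordinates.

    For substitutions the span is the single mutated position; for deletions
    it is the two residues flanking the novel junction (clipped at the
    termini).
    """
    n = len(protein_wt)
    if variant.kind == "sub":
        p = variant.position
        if not 1 <= p <= n:
            raise ValueError(f"substitution position {p} outside protein (1-{n})")
        if protein_wt[p - 1] != variant.ref:
            raise ValueError(
                f"reference mismatch at {p}: protein has {protein_wt[p - 1]!r}, "
                f"variant expects {variant.ref!r}"
            )
        mutant = protein_wt[: p - 1] + variant.alt + protein_wt[p:]
        return mutant, (p, p)
    start, stop = variant.position, variant.end or variant.position
    if not 1 <= start <= stop <= n:
        raise ValueError(f"deletion {start}-{stop} outside protein (1-{n})")
    mutant = protein_wt[: start - 1] + protein_wt[stop:]
    j = start - 1  # residue left of the junction, mutant coordinates
    lo = max(1, j)
    hi = min(len(mutant), j + 1)
    return mutant, (lo, hi)


@dataclass(frozen=True)
class PanelCandidate:
    peptide: LabeledPeptide  # light channel, coordinates in its protein form
    heavy: LabeledPeptide
    charge: int
    light_mz: float
    heavy_mz: float
    role: str  # 'mutant' | 'wild_type'

    @property
    def pair(self) -> IsotopePair:
        return IsotopePair(
            PrecursorIon(self.peptide, self.charge, self.light_mz),
            PrecursorIon(self.heavy, self.charge, self.heavy_mz),
        )


@dataclass(frozen=True)
class PanelResult:
    candidates: tuple[PanelCandidate, ...]
    excluded: tuple[tuple[str, str], ...]  # (sequence, reason)


_LABEL_FOR_PROTEASE = {
    "trypsin_p": ("K", LabelKind.HEAVY_K),
    "trypsin": ("K", LabelKind.HEAVY_K),
    "lysc": ("K", LabelKind.HEAVY_K),
    "gluc": ("E", LabelKind.HEAVY_E),
    "gluc_de": ("E", LabelKind.HEAVY_E),
}


def _site_peptides(peptides, span):
    lo, hi = span
    return [p for p in peptides if p.start <= lo and p.end >= hi]


def variant_panel(
    protein_wt: str,
    variant: Variant,
    proteases: list[str | Protease],
    protein_id: str | None = None,
    length_range: tuple[int, int] = (7, 52),
    charges: tuple[int, ...] = (2, 3),
    scan_range: tuple[float, float] = (400.0, 1000.0),
    max_missed_cleavages: int = 1,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> PanelResult:
    """Candidate light/heavy pairs covering a variant site, plus matched WT.

    For every protease the mutant protein (and the wild type) is digested and
    peptides spanning the variant site (or the novel junction of a deletion)
    are kept.  A heavy label is assigned to the C-terminal residue produced
    by the protease (K for LysC/trypsin peptides, E for GluC); candidates
    failing the length window, lacking a labelable C terminus, or whose
    precursor m/z at every allowed charge falls outside the scan range are
    excluded with a recorded reason.
    """
    mutant, mut_span = apply_variant(protein_wt, variant)
    if variant.kind == "sub":
        wt_span = (variant.position, variant.position)
    else:
        wt_span = (variant.position, variant.end or variant.position)

    candidates: list[PanelCandidate] = []
    excluded: list[tuple[str, str]] = []
    lmin, lmax = length_range
    for prot_name in proteases:
        prot = get_protease(prot_name)
        terminal, label_kind = _LABEL_FOR_PROTEASE[prot.name]
        for role, sequence, span in (
            ("mutant", mutant, mut_span),
            ("wild_type", protein_wt, wt_span),
        ):
            peptides = digest(sequence, prot, max_missed_cleavages, protein_id)
            for pep in _site_peptides(peptides, span):
                if not lmin <= len(pep) <= lmax:
                    excluded.append(
                        (pep.sequence, f"length {len(pep)} outside {lmin}-{lmax}")
                    )
                    continue
                if not pep.sequence.endswith(terminal):
                    excluded.append(
                        (pep.sequence, f"no C-terminal {terminal} for {prot.name} label")
                    )
                    continue
                heavy = pep.with_label(label_kind)
                any_charge = False
                for z in charges:
                    mz_l = precursor_mz(pep, z, table)
                    mz_h = precursor_mz(heavy, z, table)
                    if scan_range[0] <= mz_l < scan_range[1] and (
                        scan_range[0] <= mz_h < scan_range[1]
                    ):
                        any_charge = True
                        candidates.append(
                            PanelCandidate(pep, heavy, z, mz_l, mz_h, role)
                        )
                if not any_charge:
                    excluded.append(
                        (pep.sequence, f"precursor m/z outside scan range at z={charges}")
                    )
    # de-duplicate candidates emitted by several proteases/missed-cleavage paths
    seen: set[tuple] = set()
    unique: list[PanelCandidate] = []
    for c in candidates:
        key = (c.peptide.sequence, c.peptide.protease, c.charge, c.role)
        if key not in seen:
            seen.add(key)
            unique.append(c)
    return PanelResult(tuple(unique), tuple(excluded))
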