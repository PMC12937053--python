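"""Readers and writers for the plain-text formats the toolkit exchanges.

FASTA proteins (via pyteomics), variant specification TSVs, target-panel
TSVs, window-scheme CSVs (plus an instrument-paste dialect of center m/z and
isolation width for method editors), Skyline-style transition CSVs,
calibration specs, precursor-density references, peak lists and pathway
definitions.  All tabular formats round-trip through pandas.
"""

from __future__ import annotations

import pandas as pd
from pyteomics import fasta as _pfasta

from .chem import LabeledPeptide, LabelKind, PanelCandidate, Variant
from .windows import IsolationWindow, PrecursorDensity, WindowScheme

__all__ = [
    "read_fasta",
    "read_variants",
    "write_panel",
    "read_panel",
    "write_scheme",
    "read_scheme",
    "write_instrument_paste",
    "read_transitions",
    "read_calibration_spec",
    "read_density",
    "read_spectrum",
    "read_pathways",
    "read_abundance_matrix",
]


def read_fasta(path) -> dict[str, str]:
    """Protein sequences keyed by the first word of the FASTA description."""
    out: dict[str, str] = {}
    with _pfasta.read(str(path)) as reader:
        for description, sequence in reader:
            out[description.split()[0]] = sequence
    if not out:
        raise ValueError(f"no sequences found in {path}")
    return out


def read_variants(path) -> list[tuple[str, Variant]]:
    """Variant spec TSV: protein_id, type (sub|del), position, ref, alt.

    For deletions ``position`` may be a ``start-end`` range; ref/alt are
    ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "type", "position"}
    if not required <= set(df.columns):
        raise ValueError(f"variant spec must have columns {sorted(required)}")
    out: list[tuple[str, Variant]] = []
    for i, row in df.iterrows():
        kind = row["type"].strip().lower()
        pos = str(row["position"]).strip()
        if kind == "sub":
            out.append(
                (
                    row["protein_id"],
                    Variant("sub", int(pos), ref=row["ref"].strip(), alt=row["alt"].strip()),
                )
            )
        elif kind == "del":
            if "-" in pos:
                a, b = pos.split("-", 1)
            else:
                a = b = pos
            out.append((row["protein_id"], Variant("del", int(a), end=int(b))))
        else:
            raise ValueError(f"{path} line {i + 2}: unknown variant type {kind!r}")
    return out


_PANEL_COLUMNS = [
    "sequence",
    "protein_id",
    "start",
    "end",
    "protease",
    "charge",
    "label",
    "light_mz",
    "heavy_mz",
    "role",
]


def write_panel(candidates: list[PanelCandidate], path) -> None:
    rows = [
        {
            "sequence": c.peptide.sequence,
            "protein_id": c.peptide.protein_id or "",
            "start": c.peptide.start,
            "end": c.peptide.end,
            "protease": c.peptide.protease or "",
            "charge": c.charge,
            "label": c.heavy.label.kind.value,
            "light_mz": round(c.light_mz, 4),
            "heavy_mz": round(c.heavy_mz, 4),
            "role": c.role,
        }
        for c in candidates
    ]
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_panel(path) -> list[PanelCandidate]:
    df = pd.read_csv(path, sep="\t")
    out: list[PanelCandidate] = []
    for _, row in df.iterrows():
        coords = {}
        if not pd.isna(row.get("start")):
            coords = {"start": int(row["start"]), "end": int(row["end"])}
        pep = LabeledPeptide(
            row["sequence"],
            protein_id=(row.get("protein_id") or None)
            if isinstance(row.get("protein_id"), str)
            else None,
            protease=row.get("protease") if isinstance(row.get("protease"), str) else None,
            **coords,
        )
        heavy = pep.with_label(LabelKind(row["label"]))
        out.append(
            PanelCandidate(
                pep,
                heavy,
                int(row["charge"]),
                float(row["light_mz"]),
                float(row["heavy_mz"]),
                str(row.get("role", "mutant")),
            )
        )
    return out


_SCHEME_COLUMNS = ["window_id", "start_mz", "end_mz", "center_mz", "width", "kind"]


def write_scheme(scheme: WindowScheme, path) -> None:
    pd.DataFrame(scheme.to_records(), columns=_SCHEME_COLUMNS).to_csv(path, index=False)


def read_scheme(
    scheme_path, narrow_width: float = 4.0, anchor_offset: float = 1.0
) -> WindowScheme:
    df = pd.read_csv(scheme_path)
    wins = tuple(
        IsolationWindow(
            float(r["start_mz"]), float(r["end_mz"]), str(r["kind"]), int(r["window_id"])
        )
        for _, r in df.iterrows()
    )
    if not wins:
        raise ValueError(f"no windows in {scheme_path}")
    return WindowScheme(
        wins,
        min(w.start_mz for w in wins),
        max(w.end_mz for w in wins),
        narrow_width=narrow_width,
        anchor_offset=anchor_offset,
    )


def write_instrument_paste(scheme: WindowScheme, path) -> None:
    """Two-column dialect (center m/z, isolation width) for method editors."""
    df = pd.DataFrame(
        {
            "Center m/z": [round(w.center, 4) for w in scheme.windows],
            "Isolation Width": [round(w.width, 4) for w in scheme.windows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


_TRANSITION_ALIASES = {
    "replicate": ["Replicate", "Replicate Name", "replicate"],
    "peptide": [
        "Peptide",
        "Peptide Sequence",
        "Peptide Modified Sequence",
        "peptide",
    ],
    "channel": ["Isotope Label Type", "Label", "channel"],
    "fragment": ["Fragment Ion", "Transition", "fragment"],
    "area": ["Area", "Total Area", "Total Area Fragment", "area"],
    "background": ["Background", "background"],
}


def read_transitions(path) -> pd.DataFrame:
    """Transition-level peak areas, tolerant of Skyline export headers.

    Returns a frame with normalized columns ``replicate, peptide, channel,
    fragment, area, background`` where channel is ``light``/``heavy``.
    """
    df = pd.read_csv(path)
    cols = {}
    for target, aliases in _TRANSITION_ALIASES.items():
        for alias in aliases:
            if alias in df.columns:
                cols[target] = alias
                break
    missing = [k for k in ("replicate", "peptide", "channel", "fragment", "area") if k not in cols]
    if missing:
        raise ValueError(f"{path}: could not locate column(s) {missing}")
    out = pd.DataFrame(
        {
            "replicate": df[cols["replicate"]].astype(str),
            "peptide": df[cols["peptide"]].astype(str),
            "channel": df[cols["channel"]].astype(str).str.strip().str.lower(),
            "fragment": df[cols["fragment"]].astype(str),
            "area": pd.to_numeric(df[cols["area"]]),
            "background": pd.to_numeric(df[cols["background"]])
            if "background" in cols
            else 0.0,
        }
    )
    bad = ~out["channel"].isin(["light", "heavy"])
    if bad.any():
        raise ValueError(
            f"{path}: unknown isotope label type(s) {sorted(out.loc[bad, 'channel'].unique())}"
        )
    return out


def read_calibration_spec(path) -> dict[str, float]:
    """Replicate-to-nominal-amount map; columns ``replicate`` (or ``level``)
    and ``nominal_fmol``."""
    df = pd.read_csv(path, sep="\t")
    key = "replicate" if "replicate" in df.columns else "level"
    if key not in df.columns or "nominal_fmol" not in df.columns:
        raise ValueError(f"{path}: need columns replicate|level and nominal_fmol")
    return {str(r[key]): float(r["nominal_fmol"]) for _, r in df.iterrows()}


def read_density(path) -> PrecursorDensity:
    df = pd.read_csv(path, sep="\t")
    if not {"mz", "weight"} <= set(df.columns):
        raise ValueError(f"{path}: need columns mz and weight")
    return PrecursorDensity.from_arrays(df["mz"].to_numpy(), df["weight"].to_numpy())


def read_spectrum(path):
    from .metrics import Spectrum

    df = pd.read_csv(path, sep="\t")
    if not {"mz", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: need columns mz and intensity")
    return Spectrum.from_peaks(zip(df["mz"], df["intensity"]))


def read_pathways(path) -> dict[str, set[str]]:
    """Pathway definition TSV with columns ``pathway`` and ``protein_id``."""
    df = pd.read_csv(path, sep="\t")
    if not {"pathway", "protein_id"} <= set(df.columns):
        raise ValueError(f"{path}: need columns pathway and protein_id")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["pathway"]), set()).add(str(row["protein_id"]))
    return out


def read_abundance_matrix(path) -> pd.DataFrame:
    """Proteins x samples matrix of log2 intensities; blank cells = missing."""
    return pd.read_csv(path, index_col=0)
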