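"""Curated rhodopsin reference panel: loading, validation, canonical coordinates.

The panel anchors every downstream step: homology identification, family
assignment, spectral-tuning-site mapping, and the helix C--F completeness
check.  Each entry carries a family label (PR, XR, GR, BR, SRI, ActR, ESR or
other), whether the protein is an outward proton pump (PPR), the 1-based
spectral-tuning-site coordinate (PR-like families only), the inclusive helix
C--F residue interval, the absorption maximum where known, and the domain of
life of the source organism.

The bundled default panel ships as ``data/synthetic_panel.faa`` +
``data/synthetic_panel_annotation.tsv``.  Its entry IDs mirror the GenBank
accessions of the reference proteorhodopsins, xanthorhodopsins and the
*Gloeobacter* rhodopsin customarily used to delimit these families, but the
sequences themselves are synthetic stand-ins generated by seeded mutation
from a synthetic canonical PR -- they are NOT the database records.  The
coordinate system for "position 105" is fixed by ``canonical_pr_id``
(default: the first green-absorbing PR entry), and can be overridden.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
from Bio import SeqIO

FAMILIES = ("PR", "XR", "GR", "BR", "SRI", "ActR", "ESR", "other_rhodopsin")
DOMAINS = ("prokaryote", "eukaryote", "virus")
AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")
AA_LETTERS_X = AA_LETTERS | {"X"}

#: columns required in the annotation table, in canonical order
ANNOTATION_COLUMNS = (
    "ref_id",
    "family",
    "is_ppr",
    "tuning_site",
    "helix_cf_start",
    "helix_cf_end",
    "lambda_max_nm",
    "domain",
)
#: optional columns carried through when present
OPTIONAL_COLUMNS = ("taxon", "supergroup")


class PanelError(ValueError):
    """Raised when a reference panel fails validation."""


@dataclasses.dataclass(frozen=True)
class ReferenceRhodopsin:
    """One reference panel entry.

    ``tuning_site`` and ``helix_cf_span`` are 1-based inclusive coordinates
    into ``protein_seq``; ``tuning_site`` is ``None`` for non-PR-like
    families where the blue/green residue rule does not apply.
    """

    ref_id: str
    family: str
    is_ppr: bool
    protein_seq: str
    tuning_site: int | None
    helix_cf_span: tuple[int, int]
    lambda_max_nm: float | None
    domain: str
    taxon: str | None = None
    supergroup: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise PanelError(f"{self.ref_id}: unknown family {self.family!r}")
        if self.domain not in DOMAINS:
            raise PanelError(f"{self.ref_id}: unknown domain {self.domain!r}")
        if not self.protein_seq:
            raise PanelError(f"{self.ref_id}: empty protein sequence")
        bad = set(self.protein_seq) - AA_LETTERS_X
        if bad:
            raise PanelError(
                f"{self.ref_id}: non-amino-acid letters {sorted(bad)} in sequence"
            )
        n = len(self.protein_seq)
        if self.tuning_site is not None and not (1 <= self.tuning_site <= n):
            raise PanelError(
                f"{self.ref_id}: tuning_site {self.tuning_site} outside 1..{n}"
            )
        start, end = self.helix_cf_span
        if not (1 <= start < end <= n):
            raise PanelError(
                f"{self.ref_id}: helix C-F span [{start}, {end}] invalid for length {n}"
            )

    @property
    def tuning_residue(self) -> str | None:
        if self.tuning_site is None:
            return None
        return self.protein_seq[self.tuning_site - 1]


@dataclasses.dataclass(frozen=True)
class PanelIndex:
    """Validated collection of :class:`ReferenceRhodopsin` keyed by ``ref_id``.

    ``canonical_pr_id`` names the entry whose residue numbering defines
    "position 105"; it must exist and carry a tuning site.
    """

    entries: Mapping[str, ReferenceRhodopsin]
    canonical_pr_id: str

    def __post_init__(self) -> None:
        if self.canonical_pr_id not in self.entries:
            raise PanelError(
                f"canonical_pr_id {self.canonical_pr_id!r} not present in panel"
            )
        if self.entries[self.canonical_pr_id].tuning_site is None:
            raise PanelError(
                f"canonical entry {self.canonical_pr_id!r} has no tuning_site"
            )

    def __getitem__(self, ref_id: str) -> ReferenceRhodopsin:
        return self.entries[ref_id]

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self.entries

    def __iter__(self) -> Iterator[ReferenceRhodopsin]:
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def canonical(self) -> ReferenceRhodopsin:
        return self.entries[self.canonical_pr_id]

    @property
    def total_residues(self) -> int:
        """Total panel length, the Karlin-Altschul search-space 'database' size."""
        return sum(len(e.protein_seq) for e in self)

    def to_files(self, fasta_path: str | Path, annotation_path: str | Path) -> None:
        """Write the panel back to FASTA + TSV (round-trip safe)."""
        with open(fasta_path, "w") as fh:
            for entry in self:
                fh.write(f">{entry.ref_id}\n")
                seq = entry.protein_seq
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        rows = []
        for e in self:
            rows.append(
                {
                    "ref_id": e.ref_id,
                    "family": e.family,
                    "is_ppr": int(e.is_ppr),
                    "tuning_site": "" if e.tuning_site is None else e.tuning_site,
                    "helix_cf_start": e.helix_cf_span[0],
                    "helix_cf_end": e.helix_cf_span[1],
                    "lambda_max_nm": ""
                    if e.lambda_max_nm is None
                    else f"{e.lambda_max_nm:g}",
                    "domain": e.domain,
                    "taxon": e.taxon or "",
                    "supergroup": e.supergroup or "",
                }
            )
        pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


def _default_panel_paths() -> tuple[Path, Path]:
    data = resources.files("pprscope") / "data"
    return (
        Path(str(data / "synthetic_panel.faa")),
        Path(str(data / "synthetic_panel_annotation.tsv")),
    )


def load_panel(
    panel_fasta: str | Path | None = None,
    panel_annotation: str | Path | None = None,
    canonical_pr_id: str | None = None,
) -> PanelIndex:
    """Load and validate a reference panel from FASTA + annotation TSV.

    With no arguments the bundled default panel is loaded.  FASTA record IDs
    must match the annotation ``ref_id`` column exactly; every FASTA record
    needs an annotation row and vice versa.  Empty strings in the TSV encode
    nulls.  ``canonical_pr_id`` defaults to the first PR entry (file order)
    with a non-null tuning site.
    """
    if panel_fasta is None and panel_annotation is None:
        panel_fasta, panel_annotation = _default_panel_paths()
    if panel_fasta is None or panel_annotation is None:
        raise PanelError("panel_fasta and panel_annotation must be given together")

    seqs: dict[str, str] = {}
    with open(panel_fasta) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise PanelError(f"duplicate ref_id {rec.id!r} in panel FASTA")
            seqs[rec.id] = str(rec.seq).upper()

    ann = pd.read_csv(
        panel_annotation, sep="\t", dtype=str, keep_default_na=False
    )
    missing_cols = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing_cols:
        raise PanelError(f"annotation table missing columns: {sorted(missing_cols)}")
    if ann["ref_id"].duplicated().any():
        dups = ann.loc[ann["ref_id"].duplicated(), "ref_id"].tolist()
        raise PanelError(f"duplicate ref_id in annotation: {dups}")

    ann_ids = set(ann["ref_id"])
    orphans = [rid for rid in seqs if rid not in ann_ids]
    if orphans:
        raise PanelError(f"FASTA records without annotation rows: {orphans}")
    missing_seq = [rid for rid in ann["ref_id"] if rid not in seqs]
    if missing_seq:
        raise PanelError(f"annotation rows without FASTA records: {missing_seq}")

    entries: dict[str, ReferenceRhodopsin] = {}
    for row in ann.itertuples(index=False):
        rid = row.ref_id
        entries[rid] = ReferenceRhodopsin(
            ref_id=rid,
            family=row.family,
            is_ppr=row.is_ppr in ("1", "True", "true"),
            protein_seq=seqs[rid],
            tuning_site=int(row.tuning_site) if row.tuning_site != "" else None,
            helix_cf_span=(int(row.helix_cf_start), int(row.helix_cf_end)),
            lambda_max_nm=float(row.lambda_max_nm)
            if row.lambda_max_nm != ""
            else None,
            domain=row.domain,
            taxon=getattr(row, "taxon", "") or None,
            supergroup=getattr(row, "supergroup", "") or None,
        )

    if canonical_pr_id is None:
        for rid in ann["ref_id"]:
            e = entries[rid]
            if e.family == "PR" and e.tuning_site is not None:
                canonical_pr_id = rid
                break
        else:
            raise PanelError("panel has no PR entry with a tuning site")

    return PanelIndex(entries=entries, canonical_pr_id=canonical_pr_id)


def canonical_tuning_residue(panel: PanelIndex) -> str:
    """Amino acid at the tuning site of the canonical PR entry.

    This is the residue that defines the blue/green dichotomy in the panel's
    coordinate system: Gln for blue absorbers, Met/Leu for green.
    """
    residue = panel.canonical.tuning_residue
    if residue is None:  # unreachable through PanelIndex validation
        raise PanelError(
            f"canonical entry {panel.canonical_pr_id!r} has no tuning_site"
        )
    return residue
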