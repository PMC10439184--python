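"""Family assignment and blue/green spectral-tuning classification.

Proteorhodopsin variants split into blue absorbers (BPR, lambda_max = 490 nm)
and green absorbers (GPR, lambda_max = 525 nm) according to a single retinal
pocket residue: at position 105 of the canonical PR numbering, glutamine
gives a blue absorber while methionine or leucine gives a green absorber.
Each PR-family unigene is globally aligned to the canonical reference PR to
read off the residue occupying that column, and the residue rule converts it
to a spectral class.

Some database annotations are known to be wrong for particular taxa: the
dinoflagellate PRs of *Karlodinium micrum* and *Ceratium fusus* are
experimentally blue-shifted despite carrying green-type annotations.  An
override table (user-extensible TSV) corrects such calls after the residue
rule has been applied; the bundled default table holds exactly those two
taxa.
"""

from __future__ import annotations

import dataclasses
import warnings
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .panel import PanelIndex

LAMBDA_BPR_NM = 490.0
LAMBDA_GPR_NM = 525.0

BLUE_RESIDUES = frozenset("Q")
GREEN_RESIDUES = frozenset("ML")

# global-alignment gap penalties for coordinate mapping (first gap residue
# costs the open score; local alignment is avoided so the tuning column is
# always covered)
MAP_GAP_OPEN = -10.0
MAP_GAP_EXTEND = -1.0

#: families the blue/green residue rule applies to by default
PR_LIKE_DEFAULT = ("PR",)
PR_LIKE_EXTENDED = ("PR", "XR", "GR")


@dataclasses.dataclass
class RhodopsinCall:
    """Per-unigene classification result."""

    unigene_id: str
    family: str
    is_ppr: bool
    tuning_residue: str | None
    spectral_class: str  # BPR | GPR | unclassified
    lambda_max_nm: float | None
    override_applied: bool = False
    source_taxon: str | None = None


@dataclasses.dataclass(frozen=True)
class OverrideRule:
    """Force a spectral class for calls matching a taxon/unigene pattern."""

    pattern: str
    spectral_class: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.spectral_class not in ("BPR", "GPR"):
            raise ValueError(
                f"override class must be BPR or GPR, got {self.spectral_class!r}"
            )


def classify_family(
    best_hit: tuple[str, ...] | str, panel: PanelIndex
) -> tuple[str, bool]:
    """Inherit (family, is_ppr) from the best-hit reference entry."""
    ref_id = best_hit if isinstance(best_hit, str) else best_hit[0]
    if ref_id not in panel:
        raise KeyError(f"unknown ref_id {ref_id!r}")
    entry = panel[ref_id]
    return entry.family, entry.is_ppr


def _map_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = MAP_GAP_OPEN
    aligner.extend_gap_score = MAP_GAP_EXTEND
    return aligner


def map_tuning_site(query_aa: str, panel: PanelIndex) -> str | None:
    """Query residue in the alignment column of the canonical tuning site.

    The query is globally aligned (Needleman-Wunsch, BLOSUM62) to the
    canonical PR; the symbol the query contributes to the column containing
    the canonical residue at ``tuning_site`` is returned: an amino-acid
    letter, ``'-'`` when the query gaps that column, or ``None`` if the
    alignment never covers it.  The first optimal alignment enumerated by
    the aligner is used, which is deterministic for fixed inputs.
    """
    if not query_aa:
        raise ValueError("empty query sequence")
    canonical = panel.canonical
    site0 = canonical.tuning_site - 1  # type: ignore[operator]
    aligner = _map_aligner()
    alignment = aligner.align(canonical.protein_seq, query_aa.upper())[0]
    ref_idx = alignment.indices[0]
    cols = (ref_idx == site0).nonzero()[0]
    if len(cols) == 0:
        return None
    return alignment[1][int(cols[0])]


def classify_spectral(
    tuning_residue: str | None,
    family: str,
    is_ppr: bool,
    pr_like: Sequence[str] = PR_LIKE_DEFAULT,
) -> tuple[str, float | None]:
    """Residue rule: Q -> (BPR, 490 nm); M/L -> (GPR, 525 nm); else unclassified.

    Non-pump families, families outside ``pr_like``, gap symbols, ``X`` and
    unknown residues all map to ``(unclassified, None)``.  Case-insensitive.
    """
    if not is_ppr or family not in pr_like:
        return "unclassified", None
    if tuning_residue is None:
        return "unclassified", None
    residue = tuning_residue.upper()
    if residue in BLUE_RESIDUES:
        return "BPR", LAMBDA_BPR_NM
    if residue in GREEN_RESIDUES:
        return "GPR", LAMBDA_GPR_NM
    return "unclassified", None


def load_overrides(path: str | Path | None = None) -> list[OverrideRule]:
    """Load override rules from TSV (pattern, spectral_class, note).

    Without a path, the bundled default table (the two documented
    dinoflagellate corrections) is loaded.
    """
    if path is None:
        path = Path(str(resources.files("pprscope") / "data" / "overrides.tsv"))
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        OverrideRule(
            pattern=row.pattern,
            spectral_class=row.spectral_class,
            note=getattr(row, "note", ""),
        )
        for row in df.itertuples(index=False)
    ]


def apply_overrides(
    calls: Sequence[RhodopsinCall], overrides: Sequence[OverrideRule]
) -> list[RhodopsinCall]:
    """Apply literature corrections; idempotent and order-preserving.

    A rule matches when its pattern occurs (case-insensitive substring) in a
    call's ``source_taxon`` or ``unigene_id``.  Matched calls get the forced
    spectral class and wavelength and ``override_applied=True``; a rule that
    matches nothing triggers a warning, not an error.
    """
    lambda_of = {"BPR": LAMBDA_BPR_NM, "GPR": LAMBDA_GPR_NM}
    out = [dataclasses.replace(c) for c in calls]
    for rule in overrides:
        needle = rule.pattern.lower()
        matched = False
        for call in out:
            hay = f"{call.source_taxon or ''}\t{call.unigene_id}".lower()
            if needle in hay:
                matched = True
                call.spectral_class = rule.spectral_class
                call.lambda_max_nm = lambda_of[rule.spectral_class]
                call.override_applied = True
        if not matched:
            warnings.warn(
                f"override pattern {rule.pattern!r} matched no call", stacklevel=2
            )
    return out


def classify_catalog(
    catalog: pd.DataFrame,
    queries: Mapping[str, str],
    panel: PanelIndex,
    overrides: Sequence[OverrideRule] | None = None,
    include_xr_gr: bool = False,
    require_helix_coverage: bool = True,
) -> pd.DataFrame:
    """Classify every cataloged rhodopsin unigene; returns the calls table.

    ``catalog`` is the identification output; ``queries`` maps unigene IDs to
    protein sequences.  Tuning-site mapping runs only for PR-family calls
    (optionally also XR/GR with ``include_xr_gr``); the blue/green dichotomy
    is defined for proteorhodopsins.  With ``require_helix_coverage`` (the
    inclusion criterion used for classification), unigenes whose best hit
    does not span helices C--F are dropped before classification.
    """
    pr_like = PR_LIKE_EXTENDED if include_xr_gr else PR_LIKE_DEFAULT
    if require_helix_coverage and "helix_cf_covered" in catalog.columns:
        catalog = catalog[catalog["helix_cf_covered"]]
    calls: list[RhodopsinCall] = []
    for row in catalog.itertuples(index=False):
        family, is_ppr = classify_family(row.ref_id, panel)
        residue = None
        if is_ppr and family in pr_like:
            residue = map_tuning_site(queries[row.unigene_id], panel)
        spectral, lam = classify_spectral(residue, family, is_ppr, pr_like)
        calls.append(
            RhodopsinCall(
                unigene_id=row.unigene_id,
                family=family,
                is_ppr=is_ppr,
                tuning_residue=residue,
                spectral_class=spectral,
                lambda_max_nm=lam,
                source_taxon=getattr(row, "taxon", None),
            )
        )
    if overrides is None:
        overrides = load_overrides()
    if overrides:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # unmatched defaults are routine
            calls = apply_overrides(calls, overrides)
    return calls_to_frame(calls)


def calls_to_frame(calls: Sequence[RhodopsinCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(c) for c in calls],
        columns=[
            "unigene_id",
            "family",
            "is_ppr",
            "tuning_residue",
            "spectral_class",
            "lambda_max_nm",
            "override_applied",
            "source_taxon",
        ],
    )
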