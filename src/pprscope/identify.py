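"""Rhodopsin unigene identification by reference-panel homology search.

Candidate transcripts are translated (six-frame, stop-to-stop ORFs), locally
aligned against the reference panel, screened with the conventional
annotation cutoffs (E-value < 1e-5 and identity > 40%), assigned the family
and source organism of their best hit, checked for helix C--F completeness,
and finally filtered for minimal expression (TPM >= 0.1 in at least one
sample).

E-values are derived from Karlin-Altschul statistics with fixed constants
for gapped BLOSUM62 with gap open 11 / extend 1 (K = 0.041, lambda = 0.267)
and effective search space = query length x total panel residues, so results
are reproducible without an external search tool.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .panel import PanelIndex

# Karlin-Altschul parameters for gapped BLOSUM62, gap open 11 / extend 1
KA_LAMBDA = 0.267
KA_K = 0.041
GAP_OPEN = 11
GAP_EXTEND = 1

DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_IDENTITY_MIN_PCT = 40.0
DEFAULT_MIN_TPM = 0.1


@dataclasses.dataclass
class UnigeneRecord:
    """One assembled transcript entering the identification stage."""

    unigene_id: str
    aa_seq: str
    nt_seq: str | None = None
    tpm: Mapping[str, float] | None = None
    taxonomy: str | None = None
    domain_call: str = "unknown"


@dataclasses.dataclass(frozen=True)
class AlignmentHit:
    """A local alignment of a query against one panel entry.

    ``query_span``/``ref_span`` are 1-based inclusive; ``column_map`` lists
    one ``(query_pos, ref_pos)`` pair per alignment column with ``None``
    marking a gap on that side.
    """

    query_id: str
    ref_id: str
    raw_score: float
    bitscore: float
    evalue: float
    identity_pct: float
    query_span: tuple[int, int]
    ref_span: tuple[int, int]
    column_map: tuple[tuple[int | None, int | None], ...]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "local"
    # biopython charges open_gap_score for the first gap residue, so a gap of
    # length k costs GAP_OPEN + k * GAP_EXTEND, matching the usual convention.
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def bitscore_from_raw(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def evalue_from_bitscore(bitscore: float, query_len: int, db_len: int) -> float:
    # guard the exponent: 2.0**-x underflows to 0.0 for x > ~1074, fine here
    return float(query_len) * float(db_len) * 2.0 ** (-bitscore)


def translate_orfs(nt_seq: str, min_aa_len: int) -> list[str]:
    """Six-frame stop-to-stop ORFs of length >= ``min_aa_len``, longest first.

    ORFs are the translated segments ending at a stop codon (no start-codon
    requirement, mirroring how fragmentary transcript models are handled;
    segments running off the end of the frame without a stop are not
    reported).  Ties in length break by frame order (three forward then
    three reverse frames) and position, so output order is deterministic.
    """
    nt_seq = nt_seq.strip().upper()
    if not nt_seq:
        return []
    seq = Seq(nt_seq)
    frames: list[str] = []
    for strand_seq in (seq, seq.reverse_complement()):
        for offset in range(3):
            sub = strand_seq[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(sub.translate()))
    orfs: list[tuple[int, int, str]] = []
    for frame_idx, frame in enumerate(frames):
        pos = 0
        pieces = frame.split("*")
        for segment in pieces[:-1]:  # each of these is stop-terminated
            if len(segment) >= min_aa_len:
                orfs.append((frame_idx, pos, segment))
            pos += len(segment) + 1
    orfs.sort(key=lambda t: (-len(t[2]), t[0], t[1]))
    return [seg for _, _, seg in orfs]


def _hit_from_alignment(
    alignment: Align.Alignment,
    query_id: str,
    ref_id: str,
    query_len: int,
    db_len: int,
) -> AlignmentHit:
    indices = alignment.indices  # (2, n_columns), -1 marks a gap
    q_idx, r_idx = indices[0], indices[1]
    q_cols = q_idx[q_idx >= 0]
    r_cols = r_idx[r_idx >= 0]
    q_chars = np.frombuffer(alignment[0].encode(), dtype="S1")
    r_chars = np.frombuffer(alignment[1].encode(), dtype="S1")
    n_cols = len(q_idx)
    matches = int(((q_chars == r_chars) & (q_chars != b"-")).sum())
    identity_pct = 100.0 * matches / n_cols if n_cols else 0.0
    raw = float(alignment.score)
    bits = bitscore_from_raw(raw)
    column_map = tuple(
        (int(q) + 1 if q >= 0 else None, int(r) + 1 if r >= 0 else None)
        for q, r in zip(q_idx, r_idx)
    )
    return AlignmentHit(
        query_id=query_id,
        ref_id=ref_id,
        raw_score=raw,
        bitscore=bits,
        evalue=evalue_from_bitscore(bits, query_len, db_len),
        identity_pct=identity_pct,
        query_span=(int(q_cols.min()) + 1, int(q_cols.max()) + 1),
        ref_span=(int(r_cols.min()) + 1, int(r_cols.max()) + 1),
        column_map=column_map,
    )


def search_panel(
    queries: Mapping[str, str] | Iterable[UnigeneRecord],
    panel: PanelIndex,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    identity_min_pct: float = DEFAULT_IDENTITY_MIN_PCT,
) -> list[AlignmentHit]:
    """Local alignment of every query against every panel entry.

    Only hits with ``evalue < evalue_max`` AND ``identity_pct >
    identity_min_pct`` (both strict, the conventional annotation screen) are
    returned.
    """
    if not isinstance(queries, Mapping):
        queries = {rec.unigene_id: rec.aa_seq for rec in queries}
    aligner = _make_aligner()
    db_len = panel.total_residues
    hits: list[AlignmentHit] = []
    for query_id, aa_seq in queries.items():
        if not aa_seq:
            raise ValueError(f"query {query_id!r} has an empty protein sequence")
        aa_seq = aa_seq.upper()
        for entry in panel:
            alignments = aligner.align(aa_seq, entry.protein_seq)
            if alignments.score <= 0:
                continue
            hit = _hit_from_alignment(
                alignments[0], query_id, entry.ref_id, len(aa_seq), db_len
            )
            if hit.evalue < evalue_max and hit.identity_pct > identity_min_pct:
                hits.append(hit)
    return hits


def assign_best_hit(
    hits: Sequence[AlignmentHit], panel: PanelIndex
) -> tuple[str, str, str] | None:
    """Pick the best hit for one query and inherit its reference's labels.

    Best = maximal bitscore; ties break by minimal E-value then
    lexicographically smallest ``ref_id``.  Returns ``(ref_id, family,
    domain)`` or ``None`` when the hit list is empty (query excluded from the
    rhodopsin catalog).
    """
    if not hits:
        return None
    best = min(hits, key=lambda h: (-h.bitscore, h.evalue, h.ref_id))
    entry = panel[best.ref_id]
    return best.ref_id, entry.family, entry.domain


def check_helix_coverage(hit: AlignmentHit, panel: PanelIndex) -> bool:
    """True iff the hit's reference span fully contains the helix C--F span."""
    start, end = panel[hit.ref_id].helix_cf_span
    return hit.ref_span[0] <= start and hit.ref_span[1] >= end


def filter_low_expression(
    tpm_table: pd.DataFrame, threshold: float = DEFAULT_MIN_TPM
) -> list[str]:
    """IDs of unigenes with TPM >= threshold in at least one sample.

    A unigene is eliminated only when its TPM is strictly below the threshold
    in EVERY sample; a single sample at exactly the threshold keeps it.
    """
    if tpm_table.empty:
        return []
    if (tpm_table.to_numpy() < 0).any():
        raise ValueError("TPM table contains negative values")
    keep = (tpm_table >= threshold).any(axis=1)
    return tpm_table.index[keep].tolist()


def identify_rhodopsins(
    queries: Mapping[str, str],
    panel: PanelIndex,
    tpm_table: pd.DataFrame | None = None,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    identity_min_pct: float = DEFAULT_IDENTITY_MIN_PCT,
    min_tpm: float = DEFAULT_MIN_TPM,
) -> pd.DataFrame:
    """Full identification pass: search, best hit, helix check, TPM filter.

    Returns the rhodopsin catalog: one row per retained unigene with columns
    ``unigene_id, ref_id, family, domain_call, taxon, supergroup, evalue,
    identity_pct, helix_cf_covered``.  The expression filter is applied after
    annotation; queries without any passing hit are absent from the catalog.
    """
    all_hits = search_panel(queries, panel, evalue_max, identity_min_pct)
    by_query: dict[str, list[AlignmentHit]] = {}
    for hit in all_hits:
        by_query.setdefault(hit.query_id, []).append(hit)

    rows = []
    for query_id in queries:
        hits = by_query.get(query_id, [])
        assignment = assign_best_hit(hits, panel)
        if assignment is None:
            continue
        ref_id, family, domain = assignment
        best = min(hits, key=lambda h: (-h.bitscore, h.evalue, h.ref_id))
        entry = panel[ref_id]
        rows.append(
            {
                "unigene_id": query_id,
                "ref_id": ref_id,
                "family": family,
                "domain_call": domain,
                "taxon": entry.taxon,
                "supergroup": entry.supergroup,
                "evalue": best.evalue,
                "identity_pct": best.identity_pct,
                "helix_cf_covered": check_helix_coverage(best, panel),
            }
        )
    catalog = pd.DataFrame(
        rows,
        columns=[
            "unigene_id",
            "ref_id",
            "family",
            "domain_call",
            "taxon",
            "supergroup",
            "evalue",
            "identity_pct",
            "helix_cf_covered",
        ],
    )
    if tpm_table is not None and not catalog.empty:
        present = catalog["unigene_id"].isin(tpm_table.index)
        expressed = set(
            filter_low_expression(
                tpm_table.loc[catalog.loc[present, "unigene_id"]], min_tpm
            )
        )
        catalog = catalog[catalog["unigene_id"].isin(expressed)].reset_index(
            drop=True
        )
    return catalog
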