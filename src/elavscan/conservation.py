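"""Phylogenetic footprinting of ELAV binding sites across a multiple alignment.

A reference EBS is projected onto alignment columns; an orthologous species
*supports* the site when its own (ungapped) sequence contains an exact motif
match whose projected column span lies within a window of the reference
span. A site is called **ultraconserved** when at least k of the n aligned
species support it — the study criterion is k=8 of n=12 drosophilids.

"Homologous position" is operationalised as windowed column-span overlap
(default W=10 columns); a supporting match may come from a different motif
of the set than the reference match, since the criterion is "an exact
match", not the same motif. Whole-locus multi-species alignment is
delegated to external tools; the bundled Needleman–Wunsch aligner and star
MSA builder exist for tests and small synthetic data sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, CoordinateError, SpeciesLookupError
from .io import MultipleAlignment, SequenceRecord
from .motifs import EBSSite, MotifSet, scan_sequence

DEFAULT_WINDOW = 10
DEFAULT_MIN_SPECIES = 8

_GAP = "-"


@dataclass(frozen=True)
class ProjectedSite:
    """An EBS lifted to alignment-column coordinates (0-based, half-open)."""

    site: EBSSite
    col_start: int
    col_end: int


@dataclass(frozen=True)
class ConservationCall:
    site_index: int
    supporting_species: frozenset[str]
    n_supporting: int
    n_species: int
    ultraconserved: bool


def _ungapped_to_columns(gapped: str) -> np.ndarray:
    """Column index of each ungapped residue of a gapped row."""
    arr = np.frombuffer(gapped.encode(), dtype=np.uint8)
    return np.flatnonzero(arr != ord(_GAP))


def project_to_alignment(site: EBSSite, aln: MultipleAlignment) -> ProjectedSite:
    """Minimal column span whose ungapped reference content is the site."""
    cols = _ungapped_to_columns(aln.gapped(aln.ref_species))
    if site.interval.end > cols.size:
        raise CoordinateError(
            f"site {site.name} ends at {site.interval.end} but reference "
            f"{aln.ref_species!r} has only {cols.size} residues"
        )
    return ProjectedSite(
        site=site,
        col_start=int(cols[site.interval.start]),
        col_end=int(cols[site.interval.end - 1]) + 1,
    )


def species_supports_site(
    projected: ProjectedSite,
    aln: MultipleAlignment,
    species_id: str,
    motifs: MotifSet,
    window_W: int = DEFAULT_WINDOW,
) -> bool:
    """True iff the species has an exact motif match whose column span lies
    within [col_start - W, col_end + W): the homologous position, widened
    by a tolerance of W alignment columns on each side."""
    if window_W < 0:
        raise ConfigError(f"window_W must be >= 0, got {window_W}")
    gapped = aln.gapped(species_id)  # raises SpeciesLookupError if absent
    cols = _ungapped_to_columns(gapped)
    record = SequenceRecord(species_id, gapped.replace(_GAP, ""))
    lo = projected.col_start - window_W
    hi = projected.col_end + window_W
    for mm in scan_sequence(record, motifs):
        m_lo = int(cols[mm.start])
        m_hi = int(cols[mm.end - 1]) + 1
        if m_lo >= lo and m_hi <= hi:
            return True
    return False


def classify_conservation(
    sites: list[EBSSite],
    aln: MultipleAlignment,
    motifs: MotifSet,
    k: int | None = None,
    window_W: int = DEFAULT_WINDOW,
) -> list[ConservationCall]:
    """One call per site: ultraconserved ⇔ supported in ≥ k of the n species.

    k defaults to 8 only for the canonical 12-species panel; for any other
    panel size it must be given explicitly.
    """
    n = aln.n_species
    if k is None:
        if n != 12:
            raise ConfigError(
                f"k defaults to 8 only for 12 species; alignment has {n} — pass k explicitly"
            )
        k = DEFAULT_MIN_SPECIES
    if k > n:
        raise ConfigError(f"k={k} exceeds the {n} species in the alignment")
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    calls: list[ConservationCall] = []
    # precompute per-species scans once; sites reuse them
    per_species: list[tuple[str, np.ndarray, list]] = []
    for sp, gapped in aln.rows:
        cols = _ungapped_to_columns(gapped)
        rec = SequenceRecord(sp, gapped.replace(_GAP, ""))
        matches = scan_sequence(rec, motifs)
        spans = [(int(cols[mm.start]), int(cols[mm.end - 1]) + 1) for mm in matches]
        per_species.append((sp, cols, spans))
    for site in sites:
        proj = project_to_alignment(site, aln)
        lo = proj.col_start - window_W
        hi = proj.col_end + window_W
        supporting = frozenset(
            sp for sp, _, spans in per_species
            if any(m_lo >= lo and m_hi <= hi for m_lo, m_hi in spans)
        )
        calls.append(
            ConservationCall(
                site_index=site.site_index,
                supporting_species=supporting,
                n_supporting=len(supporting),
                n_species=n,
                ultraconserved=len(supporting) >= k,
            )
        )
    return calls


def pairwise_global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    match_score: float = 1.0,
    mismatch_penalty: float = -1.0,
    gap_penalty: float = -2.0,
) -> MultipleAlignment:
    """Needleman–Wunsch global alignment with a linear gap penalty.

    Traceback ties are broken deterministically: diagonal, then up (gap in
    ``b``), then left (gap in ``a``). Returns a two-row alignment with
    ``a`` as reference; the optimal score is on ``.score``.
    """
    if match_score <= 0:
        raise ConfigError(f"match_score must be positive, got {match_score}")
    sa, sb = a.seq.upper().replace("U", "T"), b.seq.upper().replace("U", "T")
    n, m = len(sa), len(sb)
    if n == 0 or m == 0:
        raise ConfigError("cannot align empty sequences")

    DIAG, UP, LEFT = 0, 1, 2
    score = np.empty((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    score[0, :] = gap_penalty * np.arange(m + 1)
    score[:, 0] = gap_penalty * np.arange(n + 1)
    ptr[0, 1:] = LEFT
    ptr[1:, 0] = UP
    for i in range(1, n + 1):
        row_prev = score[i - 1]
        row = score[i]
        ci = sa[i - 1]
        for j in range(1, m + 1):
            diag = row_prev[j - 1] + (match_score if ci == sb[j - 1] else mismatch_penalty)
            up = row_prev[j] + gap_penalty
            left = row[j - 1] + gap_penalty
            best, which = diag, DIAG
            if up > best:
                best, which = up, UP
            if left > best:
                best, which = left, LEFT
            row[j] = best
            ptr[i, j] = which

    ga: list[str] = []
    gb: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        which = ptr[i, j]
        if which == DIAG:
            ga.append(a.seq[i - 1])
            gb.append(b.seq[j - 1])
            i -= 1
            j -= 1
        elif which == UP:
            ga.append(a.seq[i - 1])
            gb.append(_GAP)
            i -= 1
        else:
            ga.append(_GAP)
            gb.append(b.seq[j - 1])
            j -= 1
    return MultipleAlignment(
        rows=[(a.id, "".join(reversed(ga))), (b.id, "".join(reversed(gb)))],
        ref_species=a.id,
        score=float(score[n, m]),
    )


def build_star_alignment(
    ref: SequenceRecord,
    others: list[SequenceRecord],
    match_score: float = 1.0,
    mismatch_penalty: float = -1.0,
    gap_penalty: float = -2.0,
) -> MultipleAlignment:
    """Stack pairwise alignments against one reference into a small MSA.

    Star construction: each ortholog is aligned to the reference with
    Needleman–Wunsch; reference gaps are reconciled by inserting, between
    consecutive reference residues, as many columns as the widest insertion
    any single species needs there. Adequate for synthetic test data; not a
    substitute for a genuine multiple aligner.
    """
    L = len(ref.seq)
    # per species: aligned char per ref position, plus insertions keyed by
    # "before ref position p" (p in 0..L)
    aligned: dict[str, list[str]] = {}
    inserts: dict[str, dict[int, str]] = {}
    for other in others:
        pw = pairwise_global_align(ref, other, match_score, mismatch_penalty, gap_penalty)
        rg, og = pw.rows[0][1], pw.rows[1][1]
        chars = [_GAP] * L
        ins: dict[int, str] = {}
        p = 0
        for rc, oc in zip(rg, og):
            if rc == _GAP:
                ins[p] = ins.get(p, "") + oc
            else:
                chars[p] = oc
                p += 1
        aligned[other.id] = chars
        inserts[other.id] = ins
    ins_width = [0] * (L + 1)
    for ins in inserts.values():
        for p, s in ins.items():
            ins_width[p] = max(ins_width[p], len(s))

    def build_row(chars: list[str], ins: dict[int, str]) -> str:
        parts: list[str] = []
        for p in range(L + 1):
            if ins_width[p]:
                s = ins.get(p, "")
                parts.append(s + _GAP * (ins_width[p] - len(s)))
            if p < L:
                parts.append(chars[p])
        return "".join(parts)

    rows = [(ref.id, build_row(list(ref.seq), {}))]
    for other in others:
        rows.append((other.id, build_row(aligned[other.id], inserts[other.id])))
    return MultipleAlignment(rows=rows, ref_species=ref.id)
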