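"""Exact-match scanning for ELAV binding motifs and merging into numbered sites.

ELAV (the founding member of the Hu family of RNA-binding proteins) binds
AU-rich elements in its target transcripts. The validated motif set comes
from two experimentally characterised ELAV targets: *Neuroglian* (five
"Nrg-like" elements) and *erect wing* (two "ewg-like" elements); an AU-rich
element (ARE) class can be added by the caller. Matching is exact,
case-insensitive and T≡U (mixed DNA/RNA sources); only the sense strand is
scanned, because the protein binds the transcript, not the genome. ``N``
never matches.

Nearby matches are merged into ELAV binding sites (EBSs) numbered 1..K in
5'→3' order on the reference sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from .errors import AmbiguityError, ConfigError
from .io import Interval, SequenceRecord

NRG_LIKE_PATTERNS = ("TTTTTGTTGT", "TTGTTTTTTT", "TTTGTTTTT", "TTTTATTTAT", "TTTTTTTT")
EWG_LIKE_PATTERNS = ("AAUUUUUU", "CAUUUUUU")

MOTIF_CLASSES = ("nrg_like", "ewg_like", "are")

DEFAULT_MERGE_GAP = 10


def t_normalize(s: str) -> str:
    """Upper-case and map U→T, the equivalence used for all matching."""
    return s.upper().replace("U", "T")


@dataclass(frozen=True)
class Motif:
    motif_id: str
    pattern: str  # stored T-normalized, upper case
    motif_class: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ConfigError(f"motif {self.motif_id!r}: empty pattern")
        if self.motif_class not in MOTIF_CLASSES:
            raise ConfigError(f"motif {self.motif_id!r}: unknown class {self.motif_class!r}")
        norm = t_normalize(self.pattern)
        if set(norm) - set("ACGT"):
            raise ConfigError(f"motif {self.motif_id!r}: pattern must be over A/C/G/T/U")
        object.__setattr__(self, "pattern", norm)


@dataclass(frozen=True)
class MotifSet:
    motifs: tuple[Motif, ...]

    def __post_init__(self) -> None:
        ids = [m.motif_id for m in self.motifs]
        if len(ids) != len(set(ids)):
            raise ConfigError("duplicate motif ids")

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    def patterns(self) -> list[str]:
        return [m.pattern for m in self.motifs]


@dataclass(frozen=True)
class MotifMatch:
    interval: Interval
    motif_id: str
    matched_text: str

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class EBSSite:
    """A merged run of motif matches, numbered 5'→3' on the reference."""

    interval: Interval
    site_index: int
    members: tuple[MotifMatch, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigError("EBS site with no member matches")

    @property
    def name(self) -> str:
        return f"EBS{self.site_index}"


def default_elav_motifs(include_are: bool = False, are_pattern: str | None = None) -> MotifSet:
    """The validated ELAV motif set: 5 Nrg-like + 2 ewg-like patterns.

    The ARE is configurable rather than hard-coded (its Ubx 3'UTR sequence
    is cited by reference, not printed); ``include_are`` without a pattern
    is a configuration error.
    """
    motifs = [
        Motif(f"nrg_{p}", p, "nrg_like") for p in NRG_LIKE_PATTERNS
    ] + [
        Motif(f"ewg_{t_normalize(p)}", p, "ewg_like") for p in EWG_LIKE_PATTERNS
    ]
    if include_are:
        if not are_pattern:
            raise ConfigError("include_are requires an ARE pattern")
        motifs.append(Motif(f"are_{t_normalize(are_pattern)}", are_pattern, "are"))
    return MotifSet(tuple(motifs))


def scan_sequence(record: SequenceRecord, motifs: MotifSet) -> list[MotifMatch]:
    """Every position where any motif matches exactly (overlaps and nestings
    all reported), sorted by (start, motif_id). Sense strand only."""
    norm = t_normalize(record.seq)
    out: list[MotifMatch] = []
    for m in motifs:
        # lookahead so overlapping occurrences of the same motif are all found
        for hit in re.finditer(f"(?={re.escape(m.pattern)})", norm):
            s = hit.start()
            e = s + len(m.pattern)
            out.append(
                MotifMatch(Interval(record.id, s, e), m.motif_id, record.seq[s:e])
            )
    out.sort(key=lambda mm: (mm.start, mm.motif_id))
    return out


def merge_matches(matches: Iterable[MotifMatch], merge_gap: int = DEFAULT_MERGE_GAP) -> list[EBSSite]:
    """Cluster matches whose intervals overlap or lie within ``merge_gap`` nt
    of each other; clusters become EBS sites numbered 1..K in 5'→3' order."""
    if merge_gap < 0:
        raise ConfigError(f"merge_gap must be >= 0, got {merge_gap}")
    matches = sorted(matches, key=lambda mm: (mm.start, mm.end))
    if not matches:
        return []
    seq_ids = {mm.interval.seq_id for mm in matches}
    if len(seq_ids) > 1:
        raise ConfigError(f"matches span multiple sequences: {sorted(seq_ids)}")
    sites: list[EBSSite] = []
    cluster: list[MotifMatch] = [matches[0]]
    cluster_end = matches[0].end
    for mm in matches[1:]:
        if mm.start <= cluster_end + merge_gap:
            cluster.append(mm)
            cluster_end = max(cluster_end, mm.end)
        else:
            sites.append(_make_site(cluster, len(sites) + 1))
            cluster = [mm]
            cluster_end = mm.end
    sites.append(_make_site(cluster, len(sites) + 1))
    return sites


def _make_site(cluster: list[MotifMatch], index: int) -> EBSSite:
    start = min(mm.start for mm in cluster)
    end = max(mm.end for mm in cluster)
    return EBSSite(Interval(cluster[0].interval.seq_id, start, end), index, tuple(cluster))


def apply_site_mutation(record: SequenceRecord, wt_core: str, mut_core: str) -> SequenceRecord:
    """Replace the unique occurrence of ``wt_core`` with ``mut_core``.

    Mirrors the site-directed mutagenesis used to destroy individual binding
    cores (e.g. site 3 ATTTTTT → AGTGTGT). The wild-type core must occur
    exactly once in the sequence under T/U-normalised, case-insensitive
    matching; zero or multiple occurrences raise :class:`AmbiguityError`.
    """
    norm_seq = t_normalize(record.seq)
    norm_core = t_normalize(wt_core)
    # count overlapping occurrences
    hits = [m.start() for m in re.finditer(f"(?={re.escape(norm_core)})", norm_seq)]
    if len(hits) == 0:
        raise AmbiguityError(f"wild-type core {wt_core!r} not found in {record.id!r}")
    if len(hits) > 1:
        raise AmbiguityError(
            f"wild-type core {wt_core!r} occurs {len(hits)} times in {record.id!r}"
        )
    s = hits[0]
    new_seq = record.seq[:s] + mut_core + record.seq[s + len(wt_core):]
    return SequenceRecord(record.id, new_seq)
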