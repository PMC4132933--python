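"""Seeded generators for synthetic inputs with the structure each stage assumes.

Every generator is a pure function of its spec and seed (bit-identical
reruns). Three kinds of data are emulated:

* **Ortholog sets** — a 12-species panel diverged from one random ancestor
  under a star phylogeny (independent lineages, per-site substitutions and
  small indels), with ELAV motifs planted at chosen ancestor positions,
  copied verbatim in a chosen subset of species and actively disrupted
  (core scrambled to a motif-free string, verified by scanning) in the
  rest. The true alignment is built from the known indel history, so the
  ground-truth conservation table is unambiguous: indels never intersect
  planted sites.
* **FISH-like image stacks** — non-overlapping bright nuclei in a nuclear
  channel, and 0–2 Gaussian foci per nucleus in a signal channel, over
  Poisson shot noise plus Gaussian read noise.
* **Count/ratio tables** — per-hemisegment Bernoulli apoptosis outcomes
  (defaults are the four published genotype conditions) and paired
  log-normal isoform-ratio replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, PlacementError
from .io import MultipleAlignment, SequenceRecord
from .motifs import MotifSet, default_elav_motifs, scan_sequence

DROSOPHILID_PANEL = (
    "dmel", "dsim", "dsec", "dyak", "dere", "dana",
    "dpse", "dper", "dwil", "dmoj", "dvir", "dgri",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# ortholog sets


@dataclass(frozen=True)
class OrthologSimSpec:
    """Conditions for a simulated ortholog panel.

    ``planted_sites`` entries are (motif_id, ancestor_position,
    retained_in); ``retained_in`` must always include the reference
    species, otherwise the site would be undiscoverable on the reference
    row and the ground truth ill-posed.
    """

    ancestor_length: int = 1000
    n_species: int = 12
    divergence: float = 0.2
    indel_rate: float = 0.01
    planted_sites: tuple[tuple[str, int, frozenset[str]], ...] = ()
    seed: int = 0
    k_ultraconserved: int = 8
    # uniform base composition by default; the AU-rich option stresses
    # chance-match behaviour of AU-rich motifs
    au_rich_background: bool = False
    motifs: MotifSet = field(default_factory=default_elav_motifs)

    def species_names(self) -> tuple[str, ...]:
        if self.n_species == 12:
            return DROSOPHILID_PANEL
        return tuple(f"sp{i:02d}" for i in range(self.n_species))

    @property
    def ref_species(self) -> str:
        return self.species_names()[0]

    def __post_init__(self) -> None:
        if self.ancestor_length < 1 or self.n_species < 1:
            raise ConfigError("ancestor_length and n_species must be positive")
        if not (0 <= self.divergence <= 1) or not (0 <= self.indel_rate <= 1):
            raise ConfigError("divergence and indel_rate must be in [0, 1]")
        names = set(self.species_names())
        patterns = {m.motif_id: m.pattern for m in self.motifs}
        spans: list[tuple[int, int]] = []
        for motif_id, pos, retained in self.planted_sites:
            if motif_id not in patterns:
                raise ConfigError(f"unknown motif id {motif_id!r}")
            end = pos + len(patterns[motif_id])
            if pos < 0 or end > self.ancestor_length:
                raise ConfigError(f"planted site {motif_id!r} at {pos} outside the ancestor")
            if not retained <= names:
                raise ConfigError(f"retained_in of {motif_id!r} names unknown species")
            if self.ref_species not in retained:
                raise ConfigError(
                    f"planted site {motif_id!r} must be retained in the reference "
                    f"species {self.ref_species!r}"
                )
            spans.append((pos, end))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ConfigError("planted sites overlap")


_AU_RICH_COMPOSITION = np.array([0.35, 0.15, 0.15, 0.35])  # A, C, G, T


def _random_seq(rng: np.random.Generator, length: int, au_rich: bool = False) -> np.ndarray:
    if au_rich:
        return _BASES[rng.choice(4, size=length, p=_AU_RICH_COMPOSITION)]
    return _BASES[rng.integers(0, 4, size=length)]


def _motif_free_scramble(
    rng: np.random.Generator, length: int, left_flank: str, right_flank: str, motifs: MotifSet
) -> str:
    """A G/C-rich replacement core that creates no motif match, even jointly
    with its flanks; verified by scanning, redrawn on failure."""
    core_start = len(left_flank)
    for _ in range(200):
        core = "".join(rng.choice(["G", "C"], size=length))
        ctx = SequenceRecord("ctx", (left_flank + core + right_flank) or "G")
        bad = any(
            mm.start < core_start + length and mm.end > core_start
            for mm in scan_sequence(ctx, motifs)
        )
        if not bad:
            return core
    raise PlacementError("could not scramble a planted core to a motif-free string")


def simulate_ortholog_set(
    spec: OrthologSimSpec,
) -> tuple[list[SequenceRecord], MultipleAlignment, pd.DataFrame]:
    """Draw an ancestor, diverge each species independently, plant/disrupt
    sites, and return (ungapped sequences, true alignment, truth table).

    The truth table has one row per planted site with its reference
    coordinates, the retained-species count and the ultraconservation
    ground truth at ``spec.k_ultraconserved``.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.ancestor_length
    names = spec.species_names()
    patterns = {m.motif_id: m.pattern for m in spec.motifs}

    ancestor = _random_seq(rng, L, au_rich=spec.au_rich_background)
    protected = np.zeros(L, dtype=bool)
    site_spans: list[tuple[str, int, int, frozenset[str]]] = []
    for motif_id, pos, retained in spec.planted_sites:
        pat = patterns[motif_id]
        ancestor[pos:pos + len(pat)] = np.frombuffer(pat.encode(), dtype=np.uint8)
        protected[pos:pos + len(pat)] = True
        site_spans.append((motif_id, pos, pos + len(pat), retained))
    site_spans.sort(key=lambda t: t[1])

    # per-species substitutions outside protected spans, then core disruption
    species_seq: dict[str, np.ndarray] = {}
    for sp in names:
        seq = ancestor.copy()
        sub_mask = (rng.random(L) < spec.divergence) & ~protected
        for idx in np.flatnonzero(sub_mask):
            choices = _BASES[_BASES != seq[idx]]
            seq[idx] = rng.choice(choices)
        for motif_id, s, e, retained in site_spans:
            if sp not in retained:
                left = seq[max(0, s - 12):s].tobytes().decode()
                right = seq[e:e + 12].tobytes().decode()
                core = _motif_free_scramble(rng, e - s, left, right, spec.motifs)
                seq[s:e] = np.frombuffer(core.encode(), dtype=np.uint8)
        species_seq[sp] = seq

    # indel history per species: deletions of single ancestor positions and
    # insertions of 1-3 nt "before position p+1"; planted spans excluded
    no_del = protected
    no_ins_before = np.zeros(L + 1, dtype=bool)
    for _, s, e, _ in site_spans:
        no_ins_before[s + 1:e] = True
    deletions: dict[str, np.ndarray] = {}
    insertions: dict[str, dict[int, str]] = {}
    for sp in names:
        dels = np.zeros(L, dtype=bool)
        ins: dict[int, str] = {}
        hits = np.flatnonzero(rng.random(L) < spec.indel_rate)
        for p in hits:
            if rng.random() < 0.5:
                if not no_del[p]:
                    dels[p] = True
            else:
                before = p + 1
                if not no_ins_before[before]:
                    ins[before] = _random_seq(rng, int(rng.integers(1, 4))).tobytes().decode()
        deletions[sp] = dels
        insertions[sp] = ins

    # column layout: before each ancestor position p an insertion block of
    # the maximum width any species needs there, then the residue column
    ins_width = np.zeros(L + 1, dtype=int)
    for sp in names:
        for p, s in insertions[sp].items():
            ins_width[p] = max(ins_width[p], len(s))
    col_of_residue = np.zeros(L, dtype=int)
    col = 0
    for p in range(L):
        col += ins_width[p]
        col_of_residue[p] = col
        col += 1
    total_cols = col + ins_width[L]

    rows: list[tuple[str, str]] = []
    for sp in names:
        row = np.full(total_cols, ord("-"), dtype=np.uint8)
        keep = ~deletions[sp]
        row[col_of_residue[keep]] = species_seq[sp][keep]
        for p, s in insertions[sp].items():
            start = (col_of_residue[p] - ins_width[p]) if p < L else total_cols - ins_width[L]
            row[start:start + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)
        rows.append((sp, row.tobytes().decode()))
    aln = MultipleAlignment(rows=rows, ref_species=spec.ref_species)
    sequences = [aln.ungapped_record(sp) for sp in names]

    # reference coordinates of planted sites (reference never deletes inside
    # a planted span, so the span is contiguous on the ungapped reference)
    ref_row = np.frombuffer(rows[0][1].encode(), dtype=np.uint8)
    not_gap = ref_row != ord("-")
    ref_pos_of_col = np.cumsum(not_gap) - 1
    truth_rows = []
    for i, (motif_id, s, e, retained) in enumerate(site_spans, start=1):
        cs, ce = col_of_residue[s], col_of_residue[e - 1] + 1
        truth_rows.append(
            {
                "site_id": i,
                "motif_id": motif_id,
                "ancestor_start": s,
                "ancestor_end": e,
                "ref_start": int(ref_pos_of_col[cs]),
                "ref_end": int(ref_pos_of_col[ce - 1]) + 1,
                "n_retained": len(retained),
                "retained": ",".join(sorted(retained)),
                "ultraconserved": len(retained) >= spec.k_ultraconserved,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "site_id", "motif_id", "ancestor_start", "ancestor_end",
            "ref_start", "ref_end", "n_retained", "retained", "ultraconserved",
        ],
    )
    return sequences, aln, truth


# ---------------------------------------------------------------------------
# image stacks


@dataclass(frozen=True)
class ImageSimSpec:
    """Conditions for a synthetic FISH stack (2D plane or 3D volume)."""

    shape: tuple[int, ...] = (128, 128)
    n_nuclei: int = 12
    foci_per_nucleus: int = 2
    focus_amplitude: tuple[float, float] = (150.0, 15.0)  # mean, sd
    focus_sigma: float = 1.0  # diffraction-limited spot at typical sampling
    background_level: float = 20.0
    read_noise_sd: float = 2.0
    poisson_noise: bool = True
    nucleus_radius: float = 10.0
    nuclear_level: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) not in (2, 3) or any(s < 16 for s in self.shape):
            raise ConfigError("shape must be 2D/3D with every axis >= 16")
        if self.foci_per_nucleus not in (0, 1, 2):
            raise ConfigError("foci_per_nucleus must be 0, 1 or 2")
        if min(self.focus_amplitude) < 0 or self.focus_sigma <= 0:
            raise ConfigError("focus amplitude/sigma must be non-negative/positive")
        if self.background_level < 0 or self.read_noise_sd < 0 or self.nucleus_radius <= 0:
            raise ConfigError("negative background, noise or radius")


def _place_nuclei(rng: np.random.Generator, spec: ImageSimSpec) -> np.ndarray:
    r = spec.nucleus_radius
    lo = np.full(len(spec.shape), r + 1.0)
    hi = np.asarray(spec.shape, dtype=float) - r - 1.0
    if (hi <= lo).any():
        raise PlacementError("image too small for the requested nucleus radius")
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < spec.n_nuclei:
        if tries > 200 * spec.n_nuclei:
            raise PlacementError(
                f"could not place {spec.n_nuclei} non-overlapping nuclei"
            )
        tries += 1
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - p) > 2 * r + 2 for p in centers):
            centers.append(c)
    return np.asarray(centers)


def simulate_foci_image(
    spec: ImageSimSpec,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Return (nuclear channel, signal channel, truth table).

    Truth lists each planted focus: owning nucleus, centroid, peak
    amplitude, and the analytic integrated amplitude A·(2πσ²)^(d/2).
    A two-allele pair is placed antipodally about the nucleus centre, so
    planted spots are well separated by construction.
    """
    rng = np.random.default_rng(spec.seed)
    ndim = len(spec.shape)
    centers = _place_nuclei(rng, spec)
    grid = np.indices(spec.shape, dtype=float)

    nuclear = np.full(spec.shape, 5.0)
    for c in centers:
        dist2 = np.zeros(spec.shape)
        for ax in range(ndim):
            dist2 += (grid[ax] - c[ax]) ** 2
        nuclear[dist2 <= spec.nucleus_radius**2] = spec.nuclear_level

    signal = np.full(spec.shape, spec.background_level)
    truth_rows = []
    amp_mean, amp_sd = spec.focus_amplitude
    win = int(np.ceil(5 * spec.focus_sigma))
    for nuc_id, c in enumerate(centers, start=1):
        # foci sit well inside the nucleus (nascent-transcription sites are
        # interior); a two-allele pair is placed antipodally about the
        # centre so planted spots are resolvable by construction
        if spec.foci_per_nucleus == 2:
            u = rng.normal(size=ndim)
            u /= np.linalg.norm(u)
            d = rng.uniform(0.3, 0.4) * spec.nucleus_radius
            placed = [c + d * u, c - d * u]
        elif spec.foci_per_nucleus == 1:
            while True:
                offset = rng.uniform(-0.4, 0.4, size=ndim) * spec.nucleus_radius
                if np.linalg.norm(offset) <= 0.4 * spec.nucleus_radius:
                    break
            placed = [c + offset]
        else:
            placed = []
        for pos in placed:
            amp = max(float(rng.normal(amp_mean, amp_sd)), 1e-3)
            sl = tuple(
                slice(max(0, int(pos[ax]) - win), min(spec.shape[ax], int(pos[ax]) + win + 1))
                for ax in range(ndim)
            )
            d2 = np.zeros(tuple(s.stop - s.start for s in sl))
            for ax in range(ndim):
                coords = np.arange(sl[ax].start, sl[ax].stop, dtype=float) - pos[ax]
                shape_ax = [1] * ndim
                shape_ax[ax] = -1
                d2 = d2 + coords.reshape(shape_ax) ** 2
            signal[sl] += amp * np.exp(-d2 / (2 * spec.focus_sigma**2))
            truth_rows.append(
                {
                    "nucleus_id": nuc_id,
                    **{f"centroid_{ax}": float(pos[ax]) for ax in range(ndim)},
                    "amplitude": amp,
                    "integrated": amp * (2 * np.pi * spec.focus_sigma**2) ** (ndim / 2),
                }
            )

    def _noisify(img: np.ndarray) -> np.ndarray:
        out = img
        if spec.poisson_noise:
            out = rng.poisson(out).astype(float)
        if spec.read_noise_sd > 0:
            out = out + rng.normal(0, spec.read_noise_sd, size=out.shape)
        return np.clip(out, 0, None)

    truth = pd.DataFrame(
        truth_rows,
        columns=["nucleus_id"]
        + [f"centroid_{ax}" for ax in range(ndim)]
        + ["amplitude", "integrated"],
    )
    return _noisify(nuclear), _noisify(signal), truth


# ---------------------------------------------------------------------------
# count/ratio tables


@dataclass(frozen=True)
class ApoptosisSimSpec:
    """Per-hemisegment Bernoulli apoptosis outcomes per genotype.

    Defaults are the four published genotype conditions (hemisegment counts
    and apoptosis fractions as printed)."""

    genotypes: tuple[tuple[str, int, float], ...] = (
        ("wild_type", 128, 0.8203),
        ("elav5", 86, 0.0930),
        ("UbxIa_rescue", 109, 0.6330),
        ("UbxIVa_rescue", 106, 0.7830),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n, p in self.genotypes:
            if n < 1:
                raise ConfigError(f"{label!r}: n must be >= 1")
            if not (0 <= p <= 1):
                raise ConfigError(f"{label!r}: p must be in [0, 1]")


def simulate_apoptosis_table(spec: ApoptosisSimSpec) -> pd.DataFrame:
    """Independent Bernoulli(p) apoptosis call per hemisegment, seeded."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label, n, p in spec.genotypes:
        outcomes = (rng.random(n) < p).astype(int)
        for i, o in enumerate(outcomes, start=1):
            rows.append({"genotype": label, "hemisegment_id": i, "apoptotic": int(o)})
    return pd.DataFrame(rows, columns=["genotype", "hemisegment_id", "apoptotic"])


def simulate_isoform_ratios(
    n_replicates: int = 3,
    mean_ratio_per_group: tuple[float, float] = (2.0, 1.0),
    cv: float = 0.1,
    seed: int = 0,
    group_labels: tuple[str, str] = ("group_a", "group_b"),
) -> pd.DataFrame:
    """Paired log-normal replicate ratios around two group means.

    The log-normal parameters are chosen so the arithmetic mean equals the
    requested group mean and the coefficient of variation equals ``cv``;
    cv=0 reproduces the means exactly. Rows are paired by replicate index.
    Default n_replicates=3 matches the study's biological-replicate design.
    """
    if cv < 0:
        raise ConfigError("cv must be >= 0")
    if min(mean_ratio_per_group) <= 0:
        raise ConfigError("group mean ratios must be positive")
    if n_replicates < 1:
        raise ConfigError("need at least one replicate")
    rng = np.random.default_rng(seed)
    out = {"replicate": np.arange(1, n_replicates + 1)}
    sigma2 = np.log1p(cv**2)
    for label, mean in zip(group_labels, mean_ratio_per_group):
        mu = np.log(mean) - sigma2 / 2
        out[label] = np.exp(rng.normal(mu, np.sqrt(sigma2), size=n_replicates))
    return pd.DataFrame(out)
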