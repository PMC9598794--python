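"""Sequence- and position-based target prediction.

miRNA -> target calls follow the canonical seed-match taxonomy: the 6mer core
is the Watson-Crick complement of miRNA nucleotides 2-7 on the target read
5'->3'; a match to position 8 upstream and/or an adenosine opposite position
1 downstream upgrade the site to 7mer-m8, 7mer-A1 or 8mer.  A target call is
conjunctive: at least one site of an accepted class AND a duplex energy at or
below the cutoff, mirroring an intersection of a seed-based and an
energy-based predictor.

The duplex energy is a simplified additive model (GC -3, AU -2, GU wobble -1
kcal/mol, +4 per unpaired/bulged base) optimized by dynamic programming; the
miRNA must be engaged end to end while target overhangs are free.  Values
are comparable only within this package, not to full nearest-neighbor
thermodynamics.

lncRNA -> gene targets come in two modes: cis (genomic gap between transcript
spans <= 100 kb, strand-agnostic, inclusive) and trans (|Pearson r| of
expression profiles >= 0.95, inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureAnnotation, SequenceSet
from .errors import ValidationError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_CLASS_RANK = {c: i for i, c in enumerate(SITE_CLASSES)}
DEFAULT_SITE_CLASSES = frozenset({"8mer", "7mer-m8", "7mer-A1"})
DEFAULT_ENERGY_CUTOFF = -20.0

PAIR_GC = -3.0
PAIR_AU = -2.0
PAIR_GU = -1.0
GAP_PENALTY = 4.0


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str, what: str):
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValidationError(f"illegal characters {sorted(bad)} in {what}")


@dataclass(frozen=True)
class SeedMatch:
    mirna_id: str
    host_id: str
    site_class: str  # 8mer | 7mer-m8 | 7mer-A1 | 6mer
    offset: int  # 0-based start of the site span on the host
    length: int  # site span length on the host
    energy: float | None = None


@dataclass(frozen=True)
class TargetPair:
    mirna_id: str
    target_id: str
    n_sites: int
    best_site_class: str
    min_energy: float


@dataclass(frozen=True)
class LncTargetPair:
    lncrna_id: str
    gene_id: str
    mode: str  # cis | trans
    distance: int | None = None  # bp, cis only
    r: float | None = None  # Pearson, trans only


# ---------------------------------------------------------------------------
# seed matching
# ---------------------------------------------------------------------------

def find_seed_sites(mirna: str, host: str, mirna_id: str = "mirna",
                    host_id: str = "host") -> list[SeedMatch]:
    """Scan ``host`` 5'->3' for canonical seed sites of ``mirna``.

    Each occurrence of the 6mer core (reverse complement of miRNA positions
    2-7) yields one site, classified by the flanking context: a match to
    position 8 immediately 5' of the core and/or an 'A' immediately 3' of it
    upgrade the class (8mer > 7mer-m8 > 7mer-A1 > 6mer).  Overlapping sites
    are all reported.
    """
    _check_alphabet(mirna, "miRNA")
    _check_alphabet(host, "host")
    if len(mirna) < 8:
        raise ValidationError(f"miRNA length {len(mirna)} < 8")
    core = revcomp(mirna[1:7])  # positions 2-7
    m8 = mirna[7].translate(_COMPLEMENT)  # complement of position 8
    sites: list[SeedMatch] = []
    pos = host.find(core)
    while pos != -1:
        has_m8 = pos > 0 and host[pos - 1] == m8
        has_a1 = pos + 6 < len(host) and host[pos + 6] == "A"
        if has_m8 and has_a1:
            cls, off, ln = "8mer", pos - 1, 8
        elif has_m8:
            cls, off, ln = "7mer-m8", pos - 1, 7
        elif has_a1:
            cls, off, ln = "7mer-A1", pos, 7
        else:
            cls, off, ln = "6mer", pos, 6
        sites.append(SeedMatch(mirna_id, host_id, cls, off, ln))
        pos = host.find(core, pos + 1)
    return sites


# ---------------------------------------------------------------------------
# duplex energy
# ---------------------------------------------------------------------------

def _pair_energy(x: str, y: str) -> float:
    """Energy of miRNA base ``x`` aligned to reverse-complemented region base
    ``y`` (equal letters correspond to a Watson-Crick pair)."""
    if x == y:
        if x in "GC":
            return PAIR_GC
        if x in "AU":
            return PAIR_AU
    if (x == "G" and y == "A") or (x == "U" and y == "C"):
        return PAIR_GU  # G:U wobble in the original duplex
    return GAP_PENALTY  # treat a mismatch like a bulged pair


def duplex_energy(mirna: str, region: str) -> float:
    """Simplified hybridization energy (kcal/mol) of a miRNA:target duplex.

    The region is reverse-complemented and aligned to the miRNA by dynamic
    programming minimizing total energy.  The miRNA is consumed in full
    (every unpaired or bulged miRNA base costs +4, so a bare seed match on an
    otherwise non-complementary region scores poorly), while region overhangs
    beyond the duplex are free.  Lower is more stable; a completely
    non-complementary pair scores > 0.
    """
    _check_alphabet(mirna, "miRNA")
    _check_alphabet(region, "site region")
    if len(region) < len(mirna) - 2:
        raise ValidationError(
            f"site region length {len(region)} < miRNA length - 2 ({len(mirna) - 2})"
        )
    x, y = mirna, revcomp(region)
    n, m = len(x), len(y)
    D = np.zeros((n + 1, m + 1))
    D[1:, 0] = GAP_PENALTY * np.arange(1, n + 1)  # miRNA bases are never free
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = min(
                D[i - 1, j - 1] + _pair_energy(x[i - 1], y[j - 1]),
                D[i - 1, j] + GAP_PENALTY,
                D[i, j - 1] + GAP_PENALTY,
            )
    return float(D[n, :].min())


def _site_region(host: str, site: SeedMatch, mirna_len: int) -> str:
    """Host window for duplex scoring: the site span plus enough upstream
    sequence for 3'-end pairing of the miRNA."""
    end = site.offset + site.length
    start = max(0, end - (mirna_len + 4))
    return host[start:end]


# ---------------------------------------------------------------------------
# target calls
# ---------------------------------------------------------------------------

def predict_mirna_targets(
    mirnas: SequenceSet,
    hosts: SequenceSet,
    energy_cutoff: float = DEFAULT_ENERGY_CUTOFF,
    site_classes: frozenset[str] | set[str] = DEFAULT_SITE_CLASSES,
) -> list[TargetPair]:
    """Call miRNA->host target pairs.

    A pair is reported iff the host carries >= 1 seed site of an accepted
    class AND the best site's duplex energy is <= ``energy_cutoff``.  Hosts
    may be 3'UTRs (mRNA targets) or lncRNA transcripts (sponge arms).
    """
    if len(mirnas) == 0 or len(hosts) == 0:
        raise ValidationError("empty sequence set for target prediction")
    unknown = set(site_classes) - set(SITE_CLASSES)
    if unknown:
        raise ValidationError(f"unknown site classes {sorted(unknown)}")
    pairs: list[TargetPair] = []
    for mid in sorted(mirnas):
        mseq = mirnas[mid]
        for hid in sorted(hosts):
            hseq = hosts[hid]
            sites = [s for s in find_seed_sites(mseq, hseq, mid, hid)
                     if s.site_class in site_classes]
            if not sites:
                continue
            energies = []
            for s in sites:
                region = _site_region(hseq, s, len(mseq))
                if len(region) < len(mseq) - 2:
                    continue  # too close to the host 5' end to score
                energies.append(duplex_energy(mseq, region))
            if not energies:
                continue
            emin = min(energies)
            if emin <= energy_cutoff:
                best = min(sites, key=lambda s: _CLASS_RANK[s.site_class])
                pairs.append(TargetPair(mid, hid, len(sites),
                                        best.site_class, emin))
    return pairs


# ---------------------------------------------------------------------------
# lncRNA targets: cis (genomic) and trans (co-expression)
# ---------------------------------------------------------------------------

def interval_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap in bp between two 0-based half-open intervals (0 if they overlap)."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


def cis_targets(
    ann: FeatureAnnotation,
    lnc_ids,
    gene_ids,
    max_distance: int = 100_000,
) -> list[LncTargetPair]:
    """lncRNA-gene pairs whose transcript spans are within ``max_distance``
    bp on the same chromosome (inclusive boundary; overlap = distance 0;
    strand ignored)."""
    lnc_ids, gene_ids = list(lnc_ids), list(gene_ids)
    missing = [f for f in lnc_ids + gene_ids if f not in ann.table.index]
    if missing:
        raise ValidationError(f"missing coordinates for {sorted(set(missing))[:10]}")
    pairs: list[LncTargetPair] = []
    for lid in sorted(lnc_ids):
        lch, ls, le = ann.interval(lid)
        for gid in sorted(gene_ids):
            if gid == lid:
                continue
            gch, gs, ge = ann.interval(gid)
            if gch != lch:
                continue
            gap = interval_gap((ls, le), (gs, ge))
            if gap <= max_distance:
                pairs.append(LncTargetPair(lid, gid, "cis", distance=gap))
    return pairs


def trans_targets(
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    r_threshold: float = 0.95,
) -> list[LncTargetPair]:
    """lncRNA-gene pairs with |Pearson r| >= ``r_threshold`` (inclusive)
    across matched samples of the two (normalized) expression tables."""
    if list(lnc_expr.columns) != list(gene_expr.columns):
        raise ValidationError("expression tables must share samples in order")
    lv = lnc_expr.to_numpy(dtype=float)
    gv = gene_expr.to_numpy(dtype=float)
    lsd = lv.std(axis=1)
    gsd = gv.std(axis=1)
    if (lsd == 0).any() or (gsd == 0).any():
        flat = list(lnc_expr.index[lsd == 0]) + list(gene_expr.index[gsd == 0])
        logger.warning("excluding zero-variance features from trans targets: %s",
                       flat[:10])
    lz = (lv - lv.mean(axis=1, keepdims=True))
    gz = (gv - gv.mean(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (lz @ gz.T) / np.outer(np.sqrt((lz**2).sum(axis=1)),
                                   np.sqrt((gz**2).sum(axis=1)))
    pairs: list[LncTargetPair] = []
    for i, lid in enumerate(lnc_expr.index):
        if lsd[i] == 0:
            continue
        for j, gid in enumerate(gene_expr.index):
            if gsd[j] == 0 or gid == lid:
                continue
            rij = float(np.clip(r[i, j], -1.0, 1.0))
            if abs(rij) >= r_threshold:
                pairs.append(LncTargetPair(lid, gid, "trans", r=rij))
    pairs.sort(key=lambda p: (p.lncrna_id, p.gene_id))
    return pairs


def intersect_target_sets(
    de_mrna_ids,
    mirna_target_ids,
    lnc_target_ids,
    mode: str = "triple",
) -> set[str]:
    """Overlap of DE mRNAs with the miRNA- and lncRNA-target gene sets.

    ``mode="triple"`` (default) is the three-way intersection; ``"either"``
    requires DE plus membership in at least one target set.
    """
    de = set(de_mrna_ids)
    mt = set(mirna_target_ids)
    lt = set(lnc_target_ids)
    if mode == "triple":
        return de & mt & lt
    if mode == "either":
        return de & (mt | lt)
    raise ValidationError(f"unknown overlap mode {mode!r}")
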