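"""Synthetic two-group multi-RNA datasets with known ground truth.

The generator emulates the study design the pipeline is built for: a high-
versus low-IMF contrast with 6 pigs per group, three count matrices (mRNA,
lncRNA, miRNA) with negative-binomial noise (variance mu + alpha mu^2),
a fraction of features carrying a planted group effect of fixed log2
magnitude, and a handful of planted ceRNA triplets whose members move
according to one of the two sponge trend models.  Each planted triplet's
miRNA gets a fully complementary binding site (which contains the canonical
8mer seed site) inserted into both the mRNA's 3'UTR and the lncRNA body, and
the lncRNA is co-located with the mRNA on the synthetic chromosome so the
co-location gate holds by construction.  IMF percentages are drawn uniformly
from the selection windows of the two groups (5.8-6.6 % high, 1.4-2.2 % low).

What this does not emulate: read-level artifacts, batch/sex covariates,
isoform structure, or realistic library sizes.  See docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cerna import SPONGE_DOWN, SPONGE_UP, TREND_MODELS, TrendModel
from .containers import (
    CountMatrix,
    FeatureAnnotation,
    SampleTable,
    SequenceSet,
)
from .errors import ConflictError, ValidationError
from .targets import revcomp

_ALPHABET = np.array(list("ACGU"))

IMF_HIGH_RANGE = (5.8, 6.6)
IMF_LOW_RANGE = (1.4, 2.2)
CIS_WINDOW = 100_000
MIN_FEATURE_SPACING = 1_100_000  # keeps non-cis pairs > 1 Mb apart


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the conditions the
    pipeline is validated under."""

    n_mrna: int = 500
    n_lncrna: int = 200
    n_mirna: int = 100
    n_per_group: int = 6
    n_triplets: int = 5
    lfc_planted: float = 2.0  # log2 group-mean ratio of planted DE features
    base_mean_range: tuple[float, float] = (50.0, 500.0)
    dispersion: float = 0.05  # NB alpha; variance = mu + alpha mu^2
    frac_null: float = 0.95  # fraction of features with no group effect
    genome_length: int = 2_500_000_000
    cis_fraction: float = 1.0  # planted lncRNA-mRNA pairs placed within 100 kb
    utr_length: int = 500
    lncrna_length: int = 1000
    sponge_latent_sd: float = 0.3  # shared per-sample factor (log2 sd)
    seed: int = 0

    def validate(self):
        bad = []
        for name in ("n_mrna", "n_lncrna", "n_mirna", "n_per_group", "n_triplets"):
            if getattr(self, name) < 0:
                bad.append(f"{name} must be >= 0")
        if self.n_triplets > min(self.n_mrna, self.n_lncrna, self.n_mirna):
            bad.append("n_triplets exceeds the smallest feature class")
        if self.dispersion < 0:
            bad.append("dispersion must be >= 0")
        if not 0.0 <= self.frac_null <= 1.0:
            bad.append("frac_null must lie in [0, 1]")
        if not 0.0 <= self.cis_fraction <= 1.0:
            bad.append("cis_fraction must lie in [0, 1]")
        lo, hi = self.base_mean_range
        if not (0 < lo <= hi):
            bad.append("base_mean_range must be positive and ordered")
        if self.lfc_planted < 0:
            bad.append("lfc_planted must be >= 0")
        if self.utr_length < 60 or self.lncrna_length < 60:
            bad.append("sequences must be >= 60 nt to host sites")
        n_features = self.n_mrna + self.n_lncrna + self.n_mirna
        if n_features and self.genome_length // (n_features + 1) < MIN_FEATURE_SPACING:
            bad.append("genome_length too small to keep non-cis features > 1 Mb apart")
        if bad:
            raise ValidationError("invalid SimulationConfig: " + "; ".join(bad), bad)


@dataclass
class GroundTruth:
    """Everything downstream recovery is scored against."""

    planted_de: dict[str, tuple[str, str]] = field(default_factory=dict)
    # feature id -> (rna class, direction)
    planted_triplets: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (lncrna, mirna, mrna, trend-model label)
    seed_sites: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    # (mirna id, host id) -> 0-based 8mer site offsets on the host
    cis_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    # (lncrna, gene, distance bp)

    def triplet_members(self) -> set[str]:
        out: set[str] = set()
        for l, m, g, _lab in self.planted_triplets:
            out |= {l, m, g}
        return out


def plant_cerna_triplet(truth: GroundTruth, ids: tuple[str, str, str],
                        model: TrendModel) -> GroundTruth:
    """Register a sponge triplet in the ground truth.

    Records the trend-consistent DE directions of the three members and
    schedules seed sites on the lncRNA and the mRNA 3'UTR (offsets are filled
    in when sequences are built).  Reusing an id in a second triplet is a
    conflict.
    """
    lnc, mir, mrna = ids
    used = truth.triplet_members()
    clash = [x for x in ids if x in used]
    if clash:
        raise ConflictError(f"ids already used in a planted triplet: {clash}")
    d_lnc, d_mir, d_mrna = model.directions
    truth.planted_de[lnc] = ("lncRNA", d_lnc)
    truth.planted_de[mir] = ("miRNA", d_mir)
    truth.planted_de[mrna] = ("mRNA", d_mrna)
    truth.planted_triplets.append((lnc, mir, mrna, model.label))
    truth.seed_sites.setdefault((mir, mrna), [])
    truth.seed_sites.setdefault((mir, lnc), [])
    return truth


@dataclass
class SyntheticDataset:
    counts: dict[str, CountMatrix]  # rna class -> matrix
    annotation: FeatureAnnotation
    sequences: dict[str, SequenceSet]  # role -> sequences
    phenotypes: SampleTable
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_ALPHABET[rng.integers(0, 4, size=length)])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB counts with mean mu and variance mu + alpha mu^2 (Poisson at 0)."""
    if alpha == 0.0:
        return rng.poisson(mu)
    size_param = 1.0 / alpha
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def _insert_site(rng: np.random.Generator, host: str, site: str,
                 occupied: list[tuple[int, int]]) -> tuple[str, int]:
    """Insert ``site`` at a random offset avoiding previous insertions and
    the host ends; returns the edited host and the insertion offset."""
    lo, hi = 30, len(host) - len(site) - 10
    if hi <= lo:
        raise ValidationError("host sequence too short to place a site")
    for _attempt in range(200):
        pos = int(rng.integers(lo, hi))
        span = (pos, pos + len(site))
        if all(span[1] <= s or span[0] >= e for s, e in occupied):
            occupied.append(span)
            return host[:pos] + site + host[pos + len(site):], pos
    raise ValidationError("could not place a non-overlapping site in 200 tries")


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full two-group dataset with ground truth.

    Same config (including seed) gives a bit-identical dataset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    mrna_ids = [f"MRNA{i + 1:04d}" for i in range(config.n_mrna)]
    lnc_ids = [f"LNC{i + 1:04d}" for i in range(config.n_lncrna)]
    mir_ids = [f"MIR{i + 1:04d}" for i in range(config.n_mirna)]
    ids_by_class = {"mRNA": mrna_ids, "lncRNA": lnc_ids, "miRNA": mir_ids}

    # --- plant triplets (members become DE with trend-consistent directions)
    truth = GroundTruth()
    for t in range(config.n_triplets):
        model = TREND_MODELS[int(rng.integers(0, len(TREND_MODELS)))]
        plant_cerna_triplet(
            truth, (lnc_ids[t], mir_ids[t], mrna_ids[t]), model
        )

    # --- remaining DE features per class
    for cls, ids in ids_by_class.items():
        n_de = round((1.0 - config.frac_null) * len(ids))
        free = [f for f in ids if f not in truth.planted_de]
        extra = max(0, n_de - (len(ids) - len(free)))
        chosen = rng.choice(len(free), size=min(extra, len(free)), replace=False)
        for i in sorted(chosen):
            direction = "up" if rng.random() < 0.5 else "down"
            truth.planted_de[free[i]] = (cls, direction)

    # --- per-sample means and counts
    n = config.n_per_group
    samples = [f"H{i + 1}" for i in range(n)] + [f"L{i + 1}" for i in range(n)]
    groups = {s: ("high" if s.startswith("H") else "low") for s in samples}
    half = config.lfc_planted / 2.0

    sponge_factor: dict[str, np.ndarray] = {}
    for (lnc, mir, mrna, _lab) in truth.planted_triplets:
        f = 2.0 ** rng.normal(0.0, config.sponge_latent_sd, size=2 * n)
        sponge_factor[lnc] = f
        sponge_factor[mrna] = f
        sponge_factor[mir] = 1.0 / f

    counts: dict[str, CountMatrix] = {}
    lo, hi = config.base_mean_range
    for cls, ids in ids_by_class.items():
        mu_base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(ids)))
        mu = np.tile(mu_base[:, None], (1, 2 * n))
        for i, fid in enumerate(ids):
            entry = truth.planted_de.get(fid)
            if entry is not None:
                sign = 1.0 if entry[1] == "up" else -1.0
                mu[i, :n] *= 2.0 ** (sign * half)   # high group
                mu[i, n:] *= 2.0 ** (-sign * half)  # low group
            if fid in sponge_factor:
                mu[i] = mu[i] * sponge_factor[fid]
        vals = _nb_draw(rng, mu, config.dispersion)
        df = pd.DataFrame(vals.astype(np.int64),
                          index=pd.Index(ids, name="id"), columns=samples)
        counts[cls] = CountMatrix(df, cls, dict(groups))

    # --- sequences (transcript-strand RNA), planted sites fully complementary
    mir_seqs = {}
    for fid in mir_ids:
        length = int(rng.integers(21, 24))
        mir_seqs[fid] = "U" + _random_seq(rng, length - 1)
    utr_seqs = {fid: _random_seq(rng, config.utr_length) for fid in mrna_ids}
    lnc_seqs = {fid: _random_seq(rng, config.lncrna_length) for fid in lnc_ids}

    occupied: dict[str, list[tuple[int, int]]] = {}
    for (lnc, mir, mrna, _lab) in truth.planted_triplets:
        site = revcomp(mir_seqs[mir])  # ends in 'A' because the miRNA starts with U
        core8_shift = len(site) - 8  # offset of the 8mer span within the site
        utr_seqs[mrna], pos = _insert_site(
            rng, utr_seqs[mrna], site, occupied.setdefault(mrna, []))
        truth.seed_sites[(mir, mrna)].append(pos + core8_shift)
        lnc_seqs[lnc], pos = _insert_site(
            rng, lnc_seqs[lnc], site, occupied.setdefault(lnc, []))
        truth.seed_sites[(mir, lnc)].append(pos + core8_shift)

    sequences = {
        "utr3": SequenceSet(utr_seqs, "utr3"),
        "lncrna": SequenceSet(lnc_seqs, "lncrna"),
        "mirna_mature": SequenceSet(mir_seqs, "mirna_mature"),
    }

    # --- genomic layout on one synthetic chromosome
    all_ids = mrna_ids + lnc_ids + mir_ids
    spacing = config.genome_length // (len(all_ids) + 1)
    slot = {fid: (i + 1) * spacing for i, fid in enumerate(all_ids)}

    lengths = {}
    exon_counts = {}
    biotypes = {}
    for fid in mrna_ids:
        lengths[fid] = 1000 + config.utr_length
        exon_counts[fid] = int(rng.integers(2, 7))
        biotypes[fid] = "protein_coding"
    for fid in lnc_ids:
        lengths[fid] = config.lncrna_length
        exon_counts[fid] = int(rng.integers(2, 5))
        biotypes[fid] = "lncRNA"
    for fid in mir_ids:
        lengths[fid] = len(mir_seqs[fid])
        exon_counts[fid] = 1
        biotypes[fid] = "miRNA"

    def genomic_span(fid: str, start: int) -> tuple[int, int]:
        # matches io.write_gtf's default exon layout (introns of 100 bp)
        end = start + lengths[fid] + (exon_counts[fid] - 1) * 100
        return start, end

    starts, ends = {}, {}
    for fid in all_ids:
        starts[fid], ends[fid] = genomic_span(fid, slot[fid])

    # co-locate planted sponge pairs within the cis window
    for (lnc, mir, mrna, _lab) in truth.planted_triplets:
        if rng.random() < config.cis_fraction:
            gap = int(rng.integers(0, CIS_WINDOW + 1))
            starts[lnc], ends[lnc] = genomic_span(lnc, ends[mrna] + gap)
            truth.cis_pairs.append((lnc, mrna, gap))

    ann_table = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": [starts[f] for f in all_ids],
            "end": [ends[f] for f in all_ids],
            "strand": "+",
            "exon_count": [exon_counts[f] for f in all_ids],
            "length": [lengths[f] for f in all_ids],
            "biotype": [biotypes[f] for f in all_ids],
        },
        index=pd.Index(all_ids, name="id"),
    )
    annotation = FeatureAnnotation(ann_table)

    # --- phenotypes
    imf = np.concatenate([
        rng.uniform(*IMF_HIGH_RANGE, size=n),
        rng.uniform(*IMF_LOW_RANGE, size=n),
    ])
    pheno = SampleTable(pd.DataFrame(
        {"group": [groups[s] for s in samples], "imf_percent": imf},
        index=pd.Index(samples, name="sample"),
    ))

    return SyntheticDataset(counts, annotation, sequences, pheno, truth, config)


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

_COUNT_FILES = {"mRNA": "counts_mrna.tsv", "lncRNA": "counts_lncrna.tsv",
                "miRNA": "counts_mirna.tsv"}
_FASTA_FILES = {"utr3": "utr3.fasta", "lncrna": "lncrna.fasta",
                "mirna_mature": "mirna.fasta"}


def write_fixture(ds: SyntheticDataset, out_dir) -> dict:
    """Write the dataset as plain-text files plus a truth manifest.

    Counts as TSV, sequences as FASTA, annotation as GTF (1-based inclusive),
    phenotypes as TSV, ground truth as JSON.  Returns the manifest dict
    (also written to ``manifest.json``).
    """
    from . import io as io_formats

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for cls, fname in _COUNT_FILES.items():
        io_formats.write_counts(ds.counts[cls], out_dir / fname)
        paths[fname] = fname
    for role, fname in _FASTA_FILES.items():
        io_formats.write_fasta(ds.sequences[role], out_dir / fname)
        paths[fname] = fname
    io_formats.write_gtf(ds.annotation, out_dir / "annotation.gtf")
    paths["annotation.gtf"] = "annotation.gtf"
    io_formats.write_sample_table(ds.phenotypes, out_dir / "phenotypes.tsv")
    paths["phenotypes.tsv"] = "phenotypes.tsv"

    truth_json = {
        "planted_de": {k: list(v) for k, v in ds.truth.planted_de.items()},
        "planted_triplets": [list(t) for t in ds.truth.planted_triplets],
        "seed_sites": [
            {"mirna": m, "host": h, "offsets": offs}
            for (m, h), offs in sorted(ds.truth.seed_sites.items())
        ],
        "cis_pairs": [list(p) for p in ds.truth.cis_pairs],
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
    paths["truth.json"] = "truth.json"

    manifest = {
        "config": asdict(ds.config),
        "files": paths,
        "n_triplets": len(ds.truth.planted_triplets),
        "triplets": [list(t) for t in ds.truth.planted_triplets],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_fixture(fixture_dir) -> SyntheticDataset:
    """Round-trip loader for :func:`write_fixture` output."""
    from . import io as io_formats

    fixture_dir = Path(fixture_dir)
    with open(fixture_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg_dict = dict(manifest["config"])
    cfg_dict["base_mean_range"] = tuple(cfg_dict["base_mean_range"])
    config = SimulationConfig(**cfg_dict)

    pheno = io_formats.read_sample_table(fixture_dir / "phenotypes.tsv")
    groups = pheno.group_map()
    counts = {
        cls: io_formats.read_counts(fixture_dir / fname, cls, groups)
        for cls, fname in _COUNT_FILES.items()
    }
    sequences = {
        role: io_formats.read_fasta(fixture_dir / fname, role)
        for role, fname in _FASTA_FILES.items()
    }
    annotation = io_formats.read_gtf(fixture_dir / "annotation.gtf")
    with open(fixture_dir / "truth.json") as fh:
        tj = json.load(fh)
    truth = GroundTruth(
        planted_de={k: tuple(v) for k, v in tj["planted_de"].items()},
        planted_triplets=[tuple(t) for t in tj["planted_triplets"]],
        seed_sites={(d["mirna"], d["host"]): list(d["offsets"])
                    for d in tj["seed_sites"]},
        cis_pairs=[tuple(p) for p in tj["cis_pairs"]],
    )
    return SyntheticDataset(counts, annotation, sequences, pheno, truth, config)
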