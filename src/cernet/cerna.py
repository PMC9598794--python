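"""ceRNA triplet assembly under the two expression-trend models.

A sponge triplet (lncRNA, miRNA, mRNA) is emitted when the lncRNA and the
mRNA both carry a predicted site for the miRNA, the mRNA sits in the
DE/target overlap set, and the three differential-expression calls follow
one of the two admissible trends: lncRNA and mRNA co-directional with the
miRNA opposite (lncRNA+|miRNA-|mRNA+ or lncRNA-|miRNA+|mRNA-).  Co-location
or co-expression evidence for the lncRNA-mRNA pair is recorded when present
and can be required via strict mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .containers import DEResult
from .errors import ValidationError
from .targets import LncTargetPair, TargetPair
from .wgcna import ModuleAssignment, ModuleTraitAssociation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrendModel:
    """A required direction pattern over (lncRNA, miRNA, mRNA)."""

    label: str
    directions: tuple[str, str, str]  # (lncRNA, miRNA, mRNA)

    def __post_init__(self):
        lnc, mir, mrna = self.directions
        if lnc != mrna or mir == lnc:
            raise ValidationError(
                "trend model must have lncRNA == mRNA direction and miRNA opposite"
            )


SPONGE_UP = TrendModel("lncRNA+|miRNA-|mRNA+", ("up", "down", "up"))
SPONGE_DOWN = TrendModel("lncRNA-|miRNA+|mRNA-", ("down", "up", "down"))
TREND_MODELS = (SPONGE_DOWN, SPONGE_UP)


def model_for(directions: tuple[str, str, str]) -> TrendModel | None:
    for m in TREND_MODELS:
        if m.directions == directions:
            return m
    return None


@dataclass(frozen=True)
class CeRNATriplet:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    model: TrendModel
    lnc_mir: TargetPair
    mir_mrna: TargetPair
    lnc_target: LncTargetPair | None = None

    @property
    def triplet_id(self) -> str:
        return f"{self.lncrna_id}|{self.mirna_id}|{self.mrna_id}"


@dataclass
class CeRNANetwork:
    triplets: list[CeRNATriplet]

    def node_table(self) -> list[tuple[str, str]]:
        """Deduplicated (id, class) rows over all triplet members."""
        nodes: dict[str, str] = {}
        for t in self.triplets:
            nodes.setdefault(t.lncrna_id, "lncRNA")
            nodes.setdefault(t.mirna_id, "miRNA")
            nodes.setdefault(t.mrna_id, "mRNA")
        return sorted(nodes.items())

    def summary(self) -> dict[str, int]:
        classes = {"lncRNA": 0, "miRNA": 0, "mRNA": 0}
        for _id, cls in self.node_table():
            classes[cls] += 1
        return {
            "n_triplets": len(self.triplets),
            "n_lncrna": classes["lncRNA"],
            "n_mirna": classes["miRNA"],
            "n_mrna": classes["mRNA"],
        }


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assign_trend(de: list[DEResult]) -> dict[str, str]:
    """Direction per feature: "up"/"down" for significant calls, "ns"
    otherwise (significance and fold-change gating happen upstream in the
    DE caller)."""
    return {r.feature_id: r.call for r in de}


def _best_pairs(pairs: list[TargetPair]) -> dict[tuple[str, str], TargetPair]:
    """Collapse multiple site records per (miRNA, host) onto the single best
    evidence (lowest energy)."""
    best: dict[tuple[str, str], TargetPair] = {}
    for p in pairs:
        key = (p.mirna_id, p.target_id)
        if key not in best or p.min_energy < best[key].min_energy:
            best[key] = p
    return best


def assemble_triplets(
    trends: dict[str, str],
    lnc_mir_pairs: list[TargetPair],
    mir_mrna_pairs: list[TargetPair],
    overlapped_mrnas: set[str],
    lnc_targets: list[LncTargetPair] | None = None,
    require_lnc_target: bool = False,
) -> list[CeRNATriplet]:
    """Emit every (lncRNA, miRNA, mRNA) combination satisfying all gates.

    Gates: the miRNA has a predicted site on both the lncRNA and the mRNA;
    the mRNA is in the overlap set; the three trend calls match one of the
    two sponge models.  With ``require_lnc_target`` the lncRNA must also be
    a cis/trans target partner of the mRNA.  Output is sorted by ids.
    """
    lnc_mir = _best_pairs(lnc_mir_pairs)
    mir_mrna = _best_pairs(mir_mrna_pairs)
    lnc_gene: dict[tuple[str, str], LncTargetPair] = {}
    for lt in lnc_targets or []:
        lnc_gene.setdefault((lt.lncrna_id, lt.gene_id), lt)

    by_mir_lnc: dict[str, list[str]] = {}
    for (mid, lid) in lnc_mir:
        by_mir_lnc.setdefault(mid, []).append(lid)
    triplets: list[CeRNATriplet] = []
    for (mid, gid), mg_pair in mir_mrna.items():
        if gid not in overlapped_mrnas:
            continue
        g_dir = trends.get(gid, "ns")
        m_dir = trends.get(mid, "ns")
        if "ns" in (g_dir, m_dir):
            continue
        for lid in by_mir_lnc.get(mid, []):
            model = model_for((trends.get(lid, "ns"), m_dir, g_dir))
            if model is None:
                continue
            evidence = lnc_gene.get((lid, gid))
            if require_lnc_target and evidence is None:
                continue
            triplets.append(
                CeRNATriplet(lid, mid, gid, model, lnc_mir[(mid, lid)],
                             mg_pair, evidence)
            )
    triplets.sort(key=lambda t: (t.lncrna_id, t.mirna_id, t.mrna_id))
    return triplets


def filter_by_module_hubs(
    triplets: list[CeRNATriplet],
    assignment: ModuleAssignment,
    trait_assoc: ModuleTraitAssociation,
    hubs: dict[str, set[str]],
) -> list[CeRNATriplet]:
    """Keep triplets whose mRNA is a hub gene of a trait-significant module
    (module-trait p < 0.05).  mRNAs absent from the module input drop the
    triplet with a warning."""
    significant = set(trait_assoc.significant_modules())
    kept = []
    for t in triplets:
        if t.mrna_id not in assignment.modules.index:
            logger.warning("mRNA %s absent from module assignment; dropping %s",
                           t.mrna_id, t.triplet_id)
            continue
        mod = assignment.modules.loc[t.mrna_id]
        if mod in significant and t.mrna_id in hubs.get(mod, set()):
            kept.append(t)
    return kept


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_network(net: CeRNANetwork, out_dir) -> dict[str, Path]:
    """Write node/edge TSVs plus a human-readable summary; returns paths."""
    from .io import write_edge_list  # deferred to avoid an import cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes_path = out_dir / "nodes.tsv"
    with open(nodes_path, "w") as fh:
        fh.write("id\tclass\n")
        for nid, cls in net.node_table():
            fh.write(f"{nid}\t{cls}\n")
    edges_path = write_edge_list(net, out_dir / "edges.tsv")
    triplets_path = out_dir / "triplets.tsv"
    with open(triplets_path, "w") as fh:
        fh.write("lncrna\tmirna\tmrna\tmodel\tmir_mrna_energy\tlnc_mir_energy\t"
                 "lnc_target_mode\n")
        for t in net.triplets:
            mode = t.lnc_target.mode if t.lnc_target else ""
            fh.write(f"{t.lncrna_id}\t{t.mirna_id}\t{t.mrna_id}\t{t.model.label}\t"
                     f"{t.mir_mrna.min_energy:.1f}\t{t.lnc_mir.min_energy:.1f}\t"
                     f"{mode}\n")
    summary_path = out_dir / "summary.txt"
    s = net.summary()
    with open(summary_path, "w") as fh:
        fh.write(f"triplets\t{s['n_triplets']}\n")
        fh.write(f"lncRNA nodes\t{s['n_lncrna']}\n")
        fh.write(f"miRNA nodes\t{s['n_mirna']}\n")
        fh.write(f"mRNA nodes\t{s['n_mrna']}\n")
    return {"nodes": nodes_path, "edges": edges_path,
            "triplets": triplets_path, "summary": summary_path}
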