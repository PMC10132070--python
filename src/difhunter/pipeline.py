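"""End-to-end orchestration and report writing.

``run_full`` composes the stages - per-copy targeting survey, element
anatomy, module discovery, identity matrix and NJ tree - into a report
bundle; writers emit deterministic TSV/JSON/GFF3/newick. Internal
coordinates are 0-based half-open; GFF3 output is 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import comparative, is_anatomy, module_discovery
from .dif_scanner import BindingSiteModel, DifSite, scan_replicon
from .insertion_analysis import analyze_insertions, targeting_report
from .seqcore import Sequence

log = logging.getLogger("difhunter")


@dataclass
class RunConfig:
    """Thresholds and modes for a pipeline run; serializable to JSON."""

    strict_sites: bool = False
    min_identity: float = 95.0
    flank_window: int = 50
    max_tsd: int = 40
    max_cargo: int = 20000
    tir_min_identical_frac: float = 0.7
    catalog_min_identity: float = 95.0
    catalog_min_coverage: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if self.flank_window <= 0 or self.max_tsd <= 0 or self.max_cargo <= 0:
            raise ValueError("windows must be positive")

    def site_model(self) -> BindingSiteModel:
        return (BindingSiteModel.strict() if self.strict_sites
                else BindingSiteModel.dif_like())

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def log_thresholds(self) -> None:
        for key, value in sorted(dataclasses.asdict(self).items()):
            log.info("config %s = %r", key, value)


@dataclass
class ReportBundle:
    """Computed tables for one run."""

    targeting: pd.DataFrame
    anatomy: pd.DataFrame
    sites: pd.DataFrame
    modules: pd.DataFrame
    identity_nt: comparative.IdentityMatrix | None = None
    tree_newick: str | None = None
    flanks: list[dict] = field(default_factory=list)


def sites_table(sites_by_rep: dict[str, list[DifSite]]) -> pd.DataFrame:
    rows = []
    for rep_id, sites in sites_by_rep.items():
        for s in sites:
            rows.append({"replicon": rep_id, "start": s.start, "end": s.end,
                         "strand": s.strand, "xerC": s.xerC, "spacer": s.spacer,
                         "xerD": s.xerD, "mm_C": s.mm_C, "mm_D": s.mm_D,
                         "dif_like": s.dif_like})
    cols = ["replicon", "start", "end", "strand", "xerC", "spacer", "xerD",
            "mm_C", "mm_D", "dif_like"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["replicon", "start", "strand"]).reset_index(drop=True)


def run_full(replicons: list[Sequence], is_queries: list[Sequence],
             catalog: list[Sequence] | None = None,
             cfg: RunConfig | None = None) -> ReportBundle:
    """Run every stage over a replicon set and a query IS set."""
    cfg = cfg or RunConfig()
    cfg.log_thresholds()
    model = cfg.site_model()

    anatomy_rows = []
    for q in is_queries:
        element = is_anatomy.characterize(
            q, min_identical_frac=cfg.tir_min_identical_frac)
        row = is_anatomy.summarize_element(element)
        row["internal_offsets"] = ";".join(
            f"{r.end}:{r.offset}" for r in element.internal)
        anatomy_rows.append(row)
    anatomy = pd.DataFrame(anatomy_rows).sort_values("name").reset_index(drop=True) \
        if anatomy_rows else pd.DataFrame(
            columns=["name", "length_bp", "tir", "tnp_aa", "ends_TGT_ACA",
                     "internal_offsets"])

    contexts = []
    sites_by_rep: dict[str, list[DifSite]] = {}
    module_rows = []
    for rep in replicons:
        sites_by_rep[rep.id] = scan_replicon(rep, model)
        for m in module_discovery.find_modules(rep, sites_by_rep[rep.id],
                                               max_cargo=cfg.max_cargo):
            match = module_discovery.match_catalog(
                m, catalog or [], min_identity=cfg.catalog_min_identity,
                min_coverage=cfg.catalog_min_coverage) if catalog else None
            module_rows.append({
                "replicon": rep.id, "cargo_start": m.cargo_start,
                "cargo_end": m.cargo_end, "type": m.module_type,
                "left_site_start": m.left_site.start,
                "right_site_start": m.right_site.start,
                "match": match.module_name if match else "novel",
                "match_identity": round(match.identity, 2) if match else "",
            })
        for q in is_queries:
            contexts.extend(analyze_insertions(
                rep, q, model=model, min_identity=cfg.min_identity,
                w=cfg.flank_window, max_tsd=cfg.max_tsd))
    targeting = targeting_report(contexts).sort_values(
        ["replicon", "start"]).reset_index(drop=True)
    modules = pd.DataFrame(module_rows, columns=[
        "replicon", "cargo_start", "cargo_end", "type", "left_site_start",
        "right_site_start", "match", "match_identity"]).sort_values(
        ["replicon", "cargo_start"]).reset_index(drop=True) \
        if module_rows else pd.DataFrame(columns=[
            "replicon", "cargo_start", "cargo_end", "type", "left_site_start",
            "right_site_start", "match", "match_identity"])

    identity_nt = None
    tree_newick = None
    if len(is_queries) >= 2:
        identity_nt = comparative.identity_matrix(is_queries, kind="nt")
        if len(is_queries) >= 3:
            tree_newick = comparative.nj_tree(identity_nt).newick()

    flanks = [{"replicon": c.copy.replicon_id, "start": c.copy.start,
               "left_flank": c.left_flank, "right_flank": c.right_flank}
              for c in contexts]
    return ReportBundle(targeting=targeting, anatomy=anatomy,
                        sites=sites_table(sites_by_rep), modules=modules,
                        identity_nt=identity_nt, tree_newick=tree_newick,
                        flanks=flanks)


def write_gff3(sites: pd.DataFrame, modules: pd.DataFrame, path: Path) -> None:
    """Sites and modules as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in sites.iterrows():
            fh.write("\t".join([
                str(r["replicon"]), "difhunter", "recombination_site",
                str(int(r["start"]) + 1), str(int(r["end"])), ".",
                str(r["strand"]), ".",
                f"ID=site_{r['replicon']}_{r['start']};mm_C={r['mm_C']};"
                f"mm_D={r['mm_D']}"]) + "\n")
        for _, r in modules.iterrows():
            fh.write("\t".join([
                str(r["replicon"]), "difhunter", "mobile_genetic_element",
                str(int(r["cargo_start"]) + 1), str(int(r["cargo_end"])), ".",
                ".", ".",
                f"ID=module_{r['replicon']}_{r['cargo_start']};"
                f"type={r['type']}"]) + "\n")


def write_reports(bundle: ReportBundle, out_dir: str | Path,
                  formats: tuple[str, ...] = ("tsv", "json", "gff3", "newick")
                  ) -> list[Path]:
    """Emit the bundle deterministically (sorted rows, stable formats)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path) -> None:
        written.append(path)

    if "tsv" in formats:
        for name, df in (("targeting", bundle.targeting),
                         ("anatomy", bundle.anatomy),
                         ("sites", bundle.sites),
                         ("modules", bundle.modules)):
            p = out / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            emit(p)
        if bundle.identity_nt is not None:
            p = out / "identity_nt.tsv"
            m = bundle.identity_nt
            pd.DataFrame(m.values, index=m.labels, columns=m.labels).round(2) \
                .to_csv(p, sep="\t")
            emit(p)
    if "json" in formats:
        p = out / "bundle.json"
        payload = {
            "targeting": bundle.targeting.to_dict(orient="records"),
            "anatomy": bundle.anatomy.to_dict(orient="records"),
            "sites": bundle.sites.to_dict(orient="records"),
            "modules": bundle.modules.to_dict(orient="records"),
            "flanks": bundle.flanks,
        }
        with open(p, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        emit(p)
    if "gff3" in formats:
        p = out / "features.gff3"
        write_gff3(bundle.sites, bundle.modules, p)
        emit(p)
    if "newick" in formats and bundle.tree_newick is not None:
        p = out / "tree.nwk"
        p.write_text(bundle.tree_newick + "\n")
        emit(p)
    return written


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, level.upper()),
                        format="%(levelname)s %(name)s: %(message)s")
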