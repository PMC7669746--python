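"""End-to-end orchestration of the stage-wise co-expression study.

One call runs the whole replica: (synthetic) cohort acquisition ->
filtering/normalisation -> per-stage differential expression,
signature rank-correlations and progressive genes -> per-phenotype MI
network inference -> cis/trans topology across cut-offs -> multi-set
intersections -> community detection with hypergeometric enrichment on
the shared and tumor-only sub-networks.  Every artifact lands under a
run directory and is indexed, together with the config and key summary
numbers, in ``manifest.json``; re-running with the same config and
seed reproduces every output byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from . import io as snio
from .core import ExpressionMatrix, GeneAnnotation, StagenetError, StageLabels
from .communities import detect_communities, enrich, enrichment_frame
from .diffexpr import (
    differential_expression,
    multi_group_contrasts,
    progressive_genes,
    rank_correlation,
)
from .netcompare import intersect, intersection_curve
from .netinfer import MIEstimatorConfig, mi_matrix
from .preprocess import filter_by_mean, log_cpm, tmm_factors
from .simulate import STUDY_BINS, SyntheticConfig, generate_cohort, make_study_config, write_cohort
from .topology import cis_trans_summary, classify_edges, fit_power_law, degree_distribution, largest_component

log = logging.getLogger("stagenet")

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and cut-offs for one pipeline run.

    Either the three input paths are given, or ``synthetic`` requests
    cohort generation.  The control phenotype is the first phenotype of
    the labels (synthetic cohorts put it first by construction).
    """

    out_dir: str
    seed: int = 0
    expression_path: str | None = None
    annotation_path: str | None = None
    labels_path: str | None = None
    gmt_path: str | None = None
    control: str = "control"
    synthetic: SyntheticConfig | None = None
    min_mean: float = 10.0
    lfc_threshold: float = 2.0
    multi_lfc_threshold: float = 0.5
    alpha: float = 0.05
    cutoffs: tuple[int, ...] = (100, 1000, 10000, 100000, 1000000)
    report_cutoff: int = 10000
    mi_config: MIEstimatorConfig = field(default_factory=MIEstimatorConfig)
    community_method: str = "infomap"
    min_community: int = 5

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise StagenetError("cutoffs must be strictly increasing")
        for name in ("min_mean", "lfc_threshold", "multi_lfc_threshold", "alpha"):
            if getattr(self, name) < 0:
                raise StagenetError(f"{name} must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "cutoffs" in raw:
            raw["cutoffs"] = tuple(int(c) for c in raw["cutoffs"])
        if "mi_config" in raw:
            raw["mi_config"] = MIEstimatorConfig(**raw["mi_config"])
        if "synthetic" in raw and raw["synthetic"] is not None:
            raise StagenetError(
                "synthetic cohorts are configured in code (see stagenet.simulate); "
                "YAML configs point at input files"
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"]["phenotypes"] = list(self.synthetic.phenotypes)
        return d


def demo_config(out_dir: str | Path, seed: int = 0) -> PipelineConfig:
    """Desk-scale study: 200 genes, 5 phenotypes, 40 samples each.

    Planted architecture: trans-rich control-only modules, cis-rich
    tumor-shared modules, two all-phenotype modules and four
    progressive genes (see :func:`stagenet.simulate.make_study_config`).
    Cut-offs {100, 300, 1000} keep the sweep proportionate to the
    ~35,000 possible edges while starting outside the constitutive
    shared program (72 pairs), below which phenotype-specific
    chromosomal structure is undefined by construction.
    """
    return PipelineConfig(
        out_dir=str(out_dir),
        seed=seed,
        synthetic=make_study_config(
            seed,
            samples_per_phenotype=40,
            module_size=10,
            n_noise_genes=42,
            include_shared_modules=True,
        ),
        cutoffs=(100, 300, 1000),
        report_cutoff=1000,
        mi_config=MIEstimatorConfig(n_bins=STUDY_BINS),
    )



def _rel(path, run_dir: Path) -> str:
    return str(Path(path).relative_to(run_dir))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StagenetError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return out
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure raises a stage-named error; artifacts written by
    earlier stages are retained.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(run_dir)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "artifacts": {},
        "summary": {},
    }

    matrix, annotation, labels, truth = _acquire(config, run_dir, manifest)
    normalized, universe = _preprocess(config, run_dir, manifest, matrix)
    de_results = _gene_level(config, run_dir, manifest, normalized, labels)
    ranked = _infer(config, run_dir, manifest, normalized, labels)
    _topology(config, run_dir, manifest, ranked, annotation)
    shared, cancer = _compare(config, run_dir, manifest, ranked, labels)
    _enrich(config, run_dir, manifest, shared, cancer, annotation, universe, truth, de_results)

    manifest_path = run_dir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("pipeline complete: %s", manifest_path)
    return run_dir


def _setup_logging(run_dir: Path) -> None:
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) and not isinstance(h, logging.FileHandler)
               for h in log.handlers):
        stream = logging.StreamHandler()
        stream.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(stream)
    for h in [h for h in log.handlers if isinstance(h, logging.FileHandler)]:
        log.removeHandler(h)
        h.close()
    fh = logging.FileHandler(run_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
    log.addHandler(fh)


@_stage("acquire")
def _acquire(config: PipelineConfig, run_dir: Path, manifest: dict):
    if config.synthetic is not None:
        matrix, annotation, labels, truth = generate_cohort(config.synthetic)
        paths = write_cohort(run_dir / "inputs", matrix, annotation, labels, truth)
        manifest["artifacts"]["inputs"] = {k: _rel(v, run_dir) for k, v in paths.items()}
        return matrix, annotation, labels, truth
    if not (config.expression_path and config.annotation_path and config.labels_path):
        raise StagenetError(
            "either synthetic generation or expression/annotation/labels paths required"
        )
    matrix = snio.read_expression(config.expression_path)
    annotation = snio.read_annotation(config.annotation_path)
    labels = snio.read_labels(config.labels_path, control=config.control)
    manifest["artifacts"]["inputs"] = {
        "expression": config.expression_path,
        "annotation": config.annotation_path,
        "labels": config.labels_path,
    }
    return matrix, annotation, labels, None


@_stage("preprocess")
def _preprocess(config, run_dir: Path, manifest, matrix: ExpressionMatrix):
    filtered = filter_by_mean(matrix, config.min_mean)
    factors = tmm_factors(filtered)
    normalized = log_cpm(filtered, factors)
    snio.write_expression(normalized, run_dir / "normalized.tsv")
    with open(run_dir / "factors.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\tfactor\n")
        for s, f in factors.items():
            fh.write(f"{s}\t{f!r}\n")
    manifest["artifacts"]["normalized"] = "normalized.tsv"
    manifest["artifacts"]["factors"] = "factors.tsv"
    manifest["summary"]["n_genes_filtered"] = normalized.n_genes
    return normalized, list(normalized.gene_ids)


@_stage("gene_level")
def _gene_level(config, run_dir: Path, manifest, normalized, labels: StageLabels):
    phenos = labels.phenotypes
    control = phenos[0]
    stages = phenos[1:]
    de_dir = run_dir / "de"
    de_dir.mkdir(exist_ok=True)
    de_results = {}
    for ph in stages:
        de = differential_expression(
            normalized, labels, ph, config.lfc_threshold, config.alpha
        )
        de_results[ph] = de
        de.to_frame().to_csv(de_dir / f"de_{ph}.tsv", sep="\t", index=False)
    manifest["artifacts"]["de"] = {ph: _rel(de_dir / f"de_{ph}.tsv", run_dir) for ph in stages}
    manifest["summary"]["n_de_genes"] = {
        ph: int((de_results[ph].status != "ns").sum()) for ph in stages
    }

    corr = {
        pa: {pb: (1.0 if pa == pb else rank_correlation(de_results[pa], de_results[pb]))
             for pb in stages}
        for pa in stages
    }
    with open(run_dir / "rank_correlation.tsv", "w", encoding="utf-8") as fh:
        fh.write("stage\t" + "\t".join(stages) + "\n")
        for pa in stages:
            fh.write(pa + "\t" + "\t".join(f"{corr[pa][pb]:.6f}" for pb in stages) + "\n")
    manifest["artifacts"]["rank_correlation"] = "rank_correlation.tsv"
    manifest["summary"]["rank_correlation"] = corr

    prog = progressive_genes(normalized, labels, phenos, config.alpha)
    with open(run_dir / "progressive.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene\tdirection\t" + "\t".join(f"mean_{ph}" for ph in phenos) + "\n")
        for pg in prog:
            fh.write(pg.gene + "\t" + pg.direction + "\t"
                     + "\t".join(f"{m:.6f}" for m in pg.means) + "\n")
    manifest["artifacts"]["progressive"] = "progressive.tsv"
    manifest["summary"]["progressive_genes"] = {pg.gene: pg.direction for pg in prog}

    multi = multi_group_contrasts(normalized, labels, config.multi_lfc_threshold, config.alpha)
    mg_dir = run_dir / "multigroup"
    mg_dir.mkdir(exist_ok=True)
    for (pa, pb), de in multi.items():
        de.to_frame().to_csv(mg_dir / f"de_{pa}_vs_{pb}.tsv", sep="\t", index=False)
    manifest["artifacts"]["multigroup"] = _rel(mg_dir, run_dir)
    return de_results


@_stage("infer")
def _infer(config, run_dir: Path, manifest, normalized, labels: StageLabels):
    net_dir = run_dir / "networks"
    net_dir.mkdir(exist_ok=True)
    max_cut = config.cutoffs[-1]
    ranked = {}
    for ph in labels.phenotypes:
        edges = mi_matrix(normalized, labels.samples(ph), config.mi_config)
        ranked[ph] = edges.top(min(max_cut, len(edges)))
        snio.write_edges(ranked[ph], net_dir / f"edges_{ph}.tsv")
    manifest["artifacts"]["networks"] = {
        ph: _rel(net_dir / f"edges_{ph}.tsv", run_dir) for ph in ranked
    }
    manifest["summary"]["n_edges"] = {ph: len(e) for ph, e in ranked.items()}
    return ranked


@_stage("topology")
def _topology(config, run_dir: Path, manifest, ranked, annotation: GeneAnnotation):
    topo_dir = run_dir / "topology"
    topo_dir.mkdir(exist_ok=True)
    cuts = [n for n in config.cutoffs if n <= max(len(e) for e in ranked.values())]
    summary: dict = {}
    trans_table: dict[int, dict[str, int]] = {n: {} for n in cuts}
    for ph, edges in ranked.items():
        summary[ph] = {}
        for n in cuts:
            net = classify_edges(edges.top(n), annotation)
            cts = cis_trans_summary(net)
            entry = {"cis_trans": cts.to_dict()}
            try:
                fit = fit_power_law(degree_distribution(net))
                entry["power_law"] = fit.to_dict()
            except StagenetError as exc:
                entry["power_law"] = {"error": str(exc)}
            summary[ph][n] = entry
            trans_table[n][ph] = cts.n_trans
        report = classify_edges(edges.top(min(config.report_cutoff, len(edges))), annotation)
        giant = largest_component(report)
        snio.export_graphml(giant, None, topo_dir / f"giant_{ph}.graphml")
    with open(topo_dir / "topology.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    phenos = list(ranked)
    with open(run_dir / "trans_counts.tsv", "w", encoding="utf-8") as fh:
        fh.write("cutoff\t" + "\t".join(phenos) + "\n")
        for n in cuts:
            fh.write(str(n) + "\t" + "\t".join(str(trans_table[n][ph]) for ph in phenos) + "\n")
    manifest["artifacts"]["topology"] = _rel(topo_dir / "topology.json", run_dir)
    manifest["artifacts"]["trans_counts"] = "trans_counts.tsv"
    manifest["summary"]["trans_counts"] = {
        str(n): trans_table[n] for n in cuts
    }


@_stage("compare")
def _compare(config, run_dir: Path, manifest, ranked, labels: StageLabels):
    control = labels.phenotypes[0]
    cuts = [n for n in config.cutoffs if n <= min(len(e) for e in ranked.values())]
    curve = intersection_curve(ranked, cuts, control_name=control)
    with open(run_dir / "intersection_curve.tsv", "w", encoding="utf-8") as fh:
        fh.write("cutoff\tproportion_shared_all\tproportion_cancer_only\n")
        for n, ps, pc in curve.points:
            fh.write(f"{n}\t{ps!r}\t{pc!r}\n")

    report_n = min(config.report_cutoff, min(len(e) for e in ranked.values()))
    sets = {ph: e.top(report_n).pairs() for ph, e in ranked.items()}
    res = intersect(sets, control_name=control)
    with open(run_dir / "venn.json", "w", encoding="utf-8") as fh:
        json.dump(res.to_dict(), fh, indent=1, sort_keys=True)

    # MI for a shared edge: its maximum across the phenotype rankings
    # (deterministic; membership itself ignores MI).
    mi_lookup: dict[tuple[str, str], float] = {}
    for e in ranked.values():
        for a, b, w in e.top(report_n):
            key = (a, b)
            mi_lookup[key] = max(mi_lookup.get(key, 0.0), w)
    from .core import MIRankedEdgeList

    shared = MIRankedEdgeList.from_records(
        [(a, b, mi_lookup[(a, b)]) for a, b in res.shared_all]
    )
    cancer = MIRankedEdgeList.from_records(
        [(a, b, mi_lookup[(a, b)]) for a, b in (res.cancer_only or set())]
    )
    snio.write_edges(shared, run_dir / "shared_all_edges.tsv")
    snio.write_edges(cancer, run_dir / "cancer_only_edges.tsv")
    manifest["artifacts"]["intersection_curve"] = "intersection_curve.tsv"
    manifest["artifacts"]["venn"] = "venn.json"
    manifest["artifacts"]["shared_all_edges"] = "shared_all_edges.tsv"
    manifest["artifacts"]["cancer_only_edges"] = "cancer_only_edges.tsv"
    manifest["summary"]["intersection"] = res.to_dict()
    manifest["summary"]["intersection_curve"] = [
        {"cutoff": n, "shared_all": ps, "cancer_only": pc} for n, ps, pc in curve.points
    ]
    return shared, cancer


@_stage("enrich")
def _enrich(config, run_dir: Path, manifest, shared, cancer, annotation, universe, truth, de_results):
    if config.gmt_path is not None:
        gene_sets = snio.read_gmt(config.gmt_path)
        gmt_src = config.gmt_path
    elif truth is not None:
        # Planted modules double as the gene-set collection, so the
        # enrichment stage has known-positive sets to recover.
        gene_sets = {
            f"module_{i:02d}": set(mod["gene_ids"])
            for i, mod in enumerate(truth.modules)
        }
        gmt_src = str(run_dir / "planted_modules.gmt")
        snio.write_gmt({k: sorted(v) for k, v in gene_sets.items()}, gmt_src)
    else:
        manifest["summary"]["enrichment"] = "skipped: no gene sets supplied"
        return

    de_status: dict[str, str] = {}
    for ph, de in de_results.items():
        for gene, status in zip(de.gene_ids, de.status):
            if status != "ns" and gene not in de_status:
                de_status[gene] = status

    for name, edges in (("shared_all", shared), ("cancer_only", cancer)):
        if len(edges) == 0:
            manifest["summary"].setdefault("enrichment", {})[name] = "empty sub-network"
            continue
        net = classify_edges(edges, annotation)
        partition = detect_communities(net, config.community_method, seed=config.seed)
        results = enrich(
            partition, gene_sets, universe, config.alpha, config.min_community
        )
        frame = enrichment_frame(results)
        out = run_dir / f"enrichment_{name}.tsv"
        frame.to_csv(out, sep="\t", index=False)
        snio.export_graphml(
            net,
            {n: {"de_status": de_status.get(n, "ns")} for n in net.nodes},
            run_dir / f"subnetwork_{name}.graphml",
        )
        manifest["artifacts"][f"enrichment_{name}"] = _rel(out, run_dir)
        manifest["summary"].setdefault("enrichment", {})[name] = {
            "n_communities": partition.n_communities,
            "n_significant": int((frame["fdr"] < config.alpha).sum()) if len(frame) else 0,
        }
    manifest["artifacts"]["gene_sets"] = (
        gmt_src if config.gmt_path is not None else _rel(gmt_src, run_dir)
    )
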