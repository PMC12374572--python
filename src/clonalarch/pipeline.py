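"""End-to-end orchestration: genotype table -> clone discrimination ->
diversity indices -> spatial architecture -> group comparisons, with CSV/JSON
outputs and a hashed run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .clones import (
    Linkage,
    MLGPartition,
    MLLPartition,
    assign_mlls,
    collapse_mlgs,
    pairwise_mlg_distances,
    pgen,
    plain_freqs,
    predict_mll_threshold,
    psex,
    round_robin_freqs,
)
from .diversity import census, diversity_report
from .io import (
    SampleSet,
    drop_incomplete_samples,
    load_layout_config,
    read_genotype_table,
)
from .spatial import (
    genet_geometries,
    identity_by_distance,
    jackknife_overlaps,
)
from .stats import all_pairs_mean_comparison, fisher_exact_2x2, rank_sum_test

logger = logging.getLogger("clonalarch")


@dataclass
class RunConfig:
    """Validated parameters of one full analysis run."""

    input_path: str
    output_dir: str
    layout_config: Optional[str] = None
    missing_mode: str = "strict"            # "strict" | "pairwise"
    linkage: str = "farthest"
    clonal_fraction: float = 0.5
    threshold: Optional[float] = None       # None -> predicted per quadrat
    bin_width: float = 1.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.missing_mode not in ("strict", "pairwise"):
            raise ValueError("missing_mode must be 'strict' or 'pairwise'")
        Linkage(self.linkage)
        if not 0 < self.clonal_fraction <= 1:
            raise ValueError("clonal_fraction must be in (0, 1]")
        if self.bin_width <= 0 or not 0 < self.alpha < 1:
            raise ValueError("invalid bin_width or alpha")


@dataclass
class QuadratAnalysis:
    """Per-quadrat intermediate results."""

    quadrat_id: str
    mlg_partition: MLGPartition
    mll_partition: MLLPartition
    threshold: float


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def analyze_quadrat(
    sample_set: SampleSet,
    quadrat_id: str,
    linkage: str = "farthest",
    clonal_fraction: float = 0.5,
    threshold: Optional[float] = None,
) -> QuadratAnalysis:
    """Clone discrimination for one quadrat: MLGs, threshold, MLLs."""
    sub = sample_set.subset(quadrat_id)
    mlgs = collapse_mlgs(sub)
    D = pairwise_mlg_distances(sub, mlgs)
    if threshold is None:
        threshold = float(predict_mll_threshold(D, clonal_fraction, linkage))
    mlls = assign_mlls(mlgs, D, threshold, linkage)
    return QuadratAnalysis(quadrat_id, mlgs, mlls, float(threshold))


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the whole workflow and write the report bundle.

    Emits per-quadrat sampling counts (table1.csv), genet counts (table2.csv),
    diversity indices (table3.csv), clone assignments, genet geometry,
    overlap and distance-identity reports, group comparisons, and a JSON
    manifest with a content hash for every output file.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    layouts = load_layout_config(config.layout_config) if config.layout_config else None

    stage = "read_input"
    try:
        sample_set = read_genotype_table(config.input_path, layouts=layouts)
        if sample_set.n_samples == 0:
            raise ValueError("input table has no records")
        n_read = sample_set.n_samples
        dropped: tuple[str, ...] = ()
        if config.missing_mode == "strict":
            sample_set, drop = drop_incomplete_samples(sample_set)
            dropped = drop.dropped_ids
            if sample_set.n_samples == 0:
                raise ValueError("no fully genotyped samples remain")

        stage = "clone_discrimination"
        analyses: dict[str, QuadratAnalysis] = {}
        assign_rows = []
        for qid in sample_set.quadrat_ids:
            qa = analyze_quadrat(
                sample_set, qid, config.linkage, config.clonal_fraction,
                config.threshold,
            )
            analyses[qid] = qa
            genet_of_sample = qa.mll_partition.genet_of_sample(qa.mlg_partition)
            for sid, mlg in qa.mlg_partition.mlg_of_sample.items():
                assign_rows.append(dict(sample_id=sid, quadrat_id=qid,
                                        mlg_id=mlg, genet_id=genet_of_sample[sid]))

        # clonal-identity probabilities of the observed MLGs (whole data set)
        freqs = (round_robin_freqs(sample_set)
                 if sample_set.panel.n_loci > 1 else plain_freqs(sample_set))
        pgen_rows = []
        all_mlgs = collapse_mlgs(sample_set)
        counts = all_mlgs.counts()
        for mlg_id in all_mlgs.mlg_ids:
            geno = all_mlgs.representative_genotype[mlg_id]
            try:
                pg = pgen(geno, freqs)
                ps = psex(pg, counts[mlg_id], all_mlgs.n_samples)
            except (KeyError, ValueError):
                pg = ps = float("nan")
            pgen_rows.append(dict(mlg_id=mlg_id, n_copies=counts[mlg_id],
                                  p_gen=pg, p_sex=ps))

        stage = "clonal_diversity"
        censuses = {}
        reports = {}
        for qid in sample_set.quadrat_ids:
            qa = analyses[qid]
            censuses[qid] = census(qa.mll_partition, qa.mlg_partition, sample_set, qid)
            reports[qid] = diversity_report(censuses[qid])

        stage = "spatial_architecture"
        geometry_rows = []
        overlaps = {}
        identity_rows = []
        for qid in sample_set.quadrat_ids:
            qa = analyses[qid]
            geoms = genet_geometries(qa.mll_partition, qa.mlg_partition,
                                     sample_set, qid)
            for g in geoms:
                geometry_rows.append(dict(
                    quadrat_id=qid, genet_id=g.genet_id, n_ramets=g.n_ramets,
                    area_m2=g.area, hull_wkt=g.hull.wkt,
                ))
            if len(geoms) >= 2:
                overlaps[qid] = jackknife_overlaps(geoms, qid)
            sub_n = censuses[qid].n_ramets
            if sub_n >= 2:
                curve = identity_by_distance(
                    qa.mll_partition, qa.mlg_partition, sample_set, qid,
                    bin_width=config.bin_width,
                )
                for k in range(len(curve.pair_counts)):
                    identity_rows.append(dict(
                        quadrat_id=qid,
                        bin_low=curve.bin_edges[k], bin_high=curve.bin_edges[k + 1],
                        n_pairs=curve.pair_counts[k], fraction_same_genet=curve.fractions[k],
                    ))

        stage = "cohort_stats"
        comparisons = _group_comparisons(sample_set, censuses, geometry_rows,
                                         config.alpha)

        stage = "write_outputs"
        files: dict[str, Path] = {}

        def write_csv(name: str, df: pd.DataFrame) -> None:
            path = outdir / name
            df.to_csv(path, index=False)
            files[name] = path

        forest_of = {
            qid: (sample_set.layouts[qid].forest_type.value
                  if sample_set.layouts[qid].forest_type else "unknown")
            for qid in sample_set.quadrat_ids
        }
        write_csv("table1_sampling.csv", pd.DataFrame([
            dict(quadrat_id=q, forest_type=forest_of[q],
                 n_on_tree=c.n_on_tree, n_on_floor=c.n_on_floor, n_total=c.n_ramets,
                 cells_on_tree=c.occupied_cells_on_tree,
                 cells_on_floor=c.occupied_cells_on_floor)
            for q, c in censuses.items()
        ]))
        write_csv("table2_genets.csv", pd.DataFrame([
            dict(quadrat_id=q, forest_type=forest_of[q], n_genets=c.n_genets,
                 n_multi_ramet_genets=c.n_multi_ramet_genets,
                 max_clone_size=c.max_clone_size,
                 clonal_ramet_pct=round(c.clonal_ramet_pct, 1))
            for q, c in censuses.items()
        ]))
        write_csv("table3_diversity.csv", pd.DataFrame([
            dict(quadrat_id=q, forest_type=forest_of[q],
                 n_ramets=r.n_ramets, n_genets=r.n_genets,
                 richness=round(r.richness, 3),
                 evenness=None if r.evenness is None else round(r.evenness, 3),
                 pareto_beta=None if r.pareto_beta is None else round(r.pareto_beta, 2),
                 pareto_p=r.pareto_p)
            for q, r in reports.items()
        ]))
        write_csv("assignments.csv", pd.DataFrame(assign_rows))
        write_csv("pgen_psex.csv", pd.DataFrame(pgen_rows))
        write_csv("genet_geometry.csv", pd.DataFrame(geometry_rows))
        if identity_rows:
            write_csv("identity_by_distance.csv", pd.DataFrame(identity_rows))
        if comparisons:
            write_csv("comparisons.csv", pd.DataFrame(comparisons))

        overlap_path = outdir / "overlaps.json"
        with overlap_path.open("w") as fh:
            json.dump({
                q: dict(n_genets=o.n_genets, total_overlaps=o.total_overlaps,
                        jackknife_values=list(o.jackknife_values),
                        jk_mean=o.jk_mean, jk_ci_low=o.jk_ci_low,
                        jk_ci_high=o.jk_ci_high)
                for q, o in overlaps.items()
            }, fh, indent=2, sort_keys=True)
        files["overlaps.json"] = overlap_path

        manifest = dict(
            tool="clonalarch",
            version=__version__,
            config=asdict(config),
            n_records_read=n_read,
            n_records_dropped=len(dropped),
            dropped_sample_ids=list(dropped),
            n_records_analyzed=sample_set.n_samples,
            quadrats={
                q: dict(
                    n_ramets=censuses[q].n_ramets,
                    n_mlgs=analyses[q].mlg_partition.n_mlgs,
                    n_genets=censuses[q].n_genets,
                    threshold=analyses[q].threshold,
                )
                for q in sample_set.quadrat_ids
            },
            outputs={name: _sha256(path) for name, path in sorted(files.items())},
        )
        manifest_path = outdir / "manifest.json"
        with manifest_path.open("w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _group_comparisons(sample_set, censuses, geometry_rows, alpha) -> list[dict]:
    """Forest-type comparisons mirroring the study's test battery."""
    rows: list[dict] = []
    forest_of = {
        qid: (sample_set.layouts[qid].forest_type.value
              if sample_set.layouts[qid].forest_type else None)
        for qid in censuses
    }
    groups = sorted({ft for ft in forest_of.values() if ft})
    if len(groups) != 2:
        return rows
    g1, g2 = groups

    # genet hull areas by forest type: rank-sum, plus all-quadrat Tukey
    areas = {qid: [] for qid in censuses}
    for row in geometry_rows:
        areas[row["quadrat_id"]].append(row["area_m2"])
    x = [a for q, vals in areas.items() if forest_of[q] == g1 for a in vals]
    y = [a for q, vals in areas.items() if forest_of[q] == g2 for a in vals]
    if x and y:
        rs = rank_sum_test(x, y, (g1, g2))
        rows.append(dict(comparison="genet_area", test="rank_sum",
                         group1=g1, group2=g2, statistic=rs.statistic,
                         p_value=rs.p_value, effect=rs.effect, detail=""))
    by_quadrat = {q: v for q, v in areas.items() if len(v) >= 2}
    if len(by_quadrat) >= 2:
        try:
            tukey = all_pairs_mean_comparison(by_quadrat, alpha)
            for pc in tukey.pairwise:
                rows.append(dict(comparison="genet_area_quadrats", test="tukey_hsd",
                                 group1=pc.group_labels[0], group2=pc.group_labels[1],
                                 statistic=pc.statistic, p_value=pc.p_value,
                                 effect=pc.effect,
                                 detail=json.dumps(tukey.letters, sort_keys=True)))
        except ValueError:
            pass

    # clonal (multi-ramet) vs single-ramet genets by forest type
    def tallies(ft):
        multi = sum(c.n_multi_ramet_genets for q, c in censuses.items()
                    if forest_of[q] == ft)
        single = sum(c.n_genets - c.n_multi_ramet_genets for q, c in censuses.items()
                     if forest_of[q] == ft)
        clonal_ramets = sum(c.n_ramets - c.n_genets for q, c in censuses.items()
                            if forest_of[q] == ft)
        total_ramets = sum(c.n_ramets for q, c in censuses.items()
                           if forest_of[q] == ft)
        return multi, single, clonal_ramets, total_ramets

    m1, s1, cr1, tr1 = tallies(g1)
    m2, s2, cr2, tr2 = tallies(g2)
    fe = fisher_exact_2x2([[m1, s1], [m2, s2]], (g1, g2))
    rows.append(dict(comparison="clonal_vs_single_genets", test="fisher_exact",
                     group1=g1, group2=g2, statistic=fe.statistic,
                     p_value=fe.p_value, effect=fe.effect,
                     detail=json.dumps(fe.extra)))
    # alternative construction on ramet tallies (clonal ramets vs totals);
    # reported for comparison, not as a substitute for the standard table
    fe_alt = fisher_exact_2x2([[cr1, tr1 - cr1], [cr2, tr2 - cr2]], (g1, g2))
    rows.append(dict(comparison="clonal_vs_sexual_ramets", test="fisher_exact",
                     group1=g1, group2=g2, statistic=fe_alt.statistic,
                     p_value=fe_alt.p_value, effect=fe_alt.effect,
                     detail=json.dumps(fe_alt.extra)))
    return rows
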