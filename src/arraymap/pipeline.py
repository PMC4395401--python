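"""End-to-end pipeline orchestration.

Stages run in a fixed order (simulate -> design -> normalize -> call ->
filter -> map -> refine -> scan); each stage writes its TSV artifacts and a
JSON run summary (input/output counts, parameters, seed) into the output
directory and can be resumed from existing stage outputs.  Everything is a
thin composition of the library modules.
"""
from __future__ import annotations

import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, filtering, io, mapping, probes, refine, scan, signal, simulate
from .config import NC, PipelineConfig

log = logging.getLogger("arraymap")

STAGES = ("simulate", "design", "normalize", "call", "filter", "map", "refine", "scan")


class PipelineError(RuntimeError):
    pass


class PipelineRun:
    """Stateful runner: stage methods read prior artifacts from ``outdir``."""

    def __init__(self, config: PipelineConfig, outdir):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    # -- helpers ----------------------------------------------------------
    def path(self, name: str) -> Path:
        return self.outdir / name

    def _summary(self, stage: str, **info):
        info.update(stage=stage, seed=self.config.seed,
                    timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))
        io.write_json(self.path(f"{stage}_summary.json"), info)

    def _load_genotypes(self, name):
        p = self.path(name)
        if not p.exists():
            raise PipelineError(f"missing input {p}; run the earlier stage first")
        return io.read_genotypes(p)

    # -- stages -----------------------------------------------------------
    def stage_simulate(self):
        cfg = self.config.sim
        calls, truth = simulate.simulate_ril_population(cfg)
        signals = simulate.simulate_array_signals(calls, cfg)
        world = simulate.simulate_design_world(cfg)
        io.write_genotypes(self.path("truth_genotypes.tsv"), truth.genotypes,
                           truth.markers)
        truth.markers.rename_axis("marker_id").to_csv(
            self.path("truth_markers.tsv"), sep="\t", float_format="%.6f")
        io.write_signals(self.path("signals_test.tsv"), signals.test)
        io.write_signals(self.path("signals_training.tsv"), signals.training)
        io.write_pileup(self.path("pileup.tsv"), world.pileup)
        io.write_fasta(self.path("reference.fasta"), world.reference)
        self.path("annotation.gff3").write_text(world.annotation_gff3)
        self._signals = signals
        self._truth = truth
        self._summary("simulate", n_markers=len(truth.markers),
                      n_rils=cfg.n_rils, generations=cfg.generations,
                      n_pileup_rows=len(world.pileup))
        return calls, truth, signals, world

    def stage_design(self):
        pileup = io.read_pileup(self.path("pileup.tsv"))
        reference = io.read_fasta(self.path("reference.fasta"))
        selected = probes.select_window_snps(
            pileup, window_bp=self.config.probe_window_bp,
            min_qual=self.config.probe_min_qual)
        params = probes.ThermoParams(ctx=self.config.probe_ctx)
        designs = []
        pad = probes.MAX_PROBE_LEN // 2 + 1
        for _, row in selected.iterrows():
            seq = reference[str(row["chrom"])]
            center = int(row["pos"]) - 1
            if center < pad or center >= len(seq) - pad:
                continue
            flank = seq[center - pad:center + pad + 1]
            designs.append(probes.design_probes(
                row, flank, params, target_tm=self.config.probe_target_tm,
                snp_offset=pad))
        frame = probes.designs_to_frame(designs)
        if designs:
            snp_meta = frame[["snp_id", "chrom", "pos"]].drop_duplicates()
            contexts = probes.annotate_snp_context(snp_meta, self.path("annotation.gff3"))
            ctx_map = dict(zip(snp_meta["snp_id"], contexts))
            frame["context"] = frame["snp_id"].map(ctx_map)
        frame.to_csv(self.path("probe_design.tsv"), sep="\t", index=False,
                     float_format="%.3f")
        self._summary("design", n_candidates=len(pileup), n_selected=len(selected),
                      n_designed=len(designs))
        return frame

    def stage_normalize(self):
        signals = getattr(self, "_signals", None)
        if signals is None:
            test = io.read_signals(self.path("signals_test.tsv"))
            training = io.read_signals(self.path("signals_training.tsv"))
            _, labels = simulate.training_sample_names()
            rng = np.random.default_rng(0)
            signals = simulate.ArraySignals(
                test=test, training=training, training_labels=labels,
                layout=simulate._default_layout(test.snp_ids, rng))
        test_s, train_s = signal.preprocess(signals)
        self._test_summ, self._train_summ = test_s, train_s
        mask_rows = np.argwhere(test_s.mask)
        pd.DataFrame({
            "snp_id": [test_s.snp_ids[i] for i, _ in mask_rows],
            "sample": [test_s.samples[j] for _, j in mask_rows],
            "masked": True,
        }).to_csv(self.path("mask.tsv"), sep="\t", index=False)
        io.write_matrix(self.path("summarized_A.tsv"),
                        pd.DataFrame(test_s.signal_a, index=test_s.snp_ids,
                                     columns=test_s.samples))
        io.write_matrix(self.path("summarized_B.tsv"),
                        pd.DataFrame(test_s.signal_b, index=test_s.snp_ids,
                                     columns=test_s.samples))
        self._summary("normalize", n_snps=len(test_s.snp_ids),
                      n_arrays=len(test_s.samples) + len(train_s.samples),
                      masked_entries=int(test_s.mask.sum()))
        return test_s, train_s

    def stage_call(self):
        test_s, train_s = getattr(self, "_test_summ", None), getattr(self, "_train_summ", None)
        if test_s is None:
            raise PipelineError("normalize stage must run in-process before call")
        _, labels = simulate.training_sample_names()
        models = calling.fit_training_models(
            train_s, labels, shrinkage=self.config.call.shrinkage)
        calls, confs = calling.call_genotypes(
            test_s, models, nc_threshold=self.config.call.nc_threshold)
        self._models = models
        markers = getattr(self, "_truth", None)
        meta = markers.markers if markers is not None else None
        io.write_genotypes(self.path("calls.tsv"), calls, meta)
        io.write_matrix(self.path("confidences.tsv"), confs)
        models.summary_frame().to_csv(self.path("training_models.tsv"), sep="\t",
                                      float_format="%.4f")
        n_gts = int((models.gts_status != calling.REJECTED).sum())
        one_off = int((models.gts_status == calling.GTS_ONE_OFF).sum())
        self._summary("call", n_snps=len(models.snp_ids), n_gts=n_gts,
                      gts_one_off=one_off,
                      nc_fraction=float((calls == NC).to_numpy().mean()))
        return calls, confs, models

    def stage_filter(self):
        calls, meta = self._load_genotypes("calls.tsv")
        confs = io.read_matrix(self.path("confidences.tsv"))
        report = filtering.FilterReport()
        fcfg = self.config.filter
        models = getattr(self, "_models", None)
        if models is not None:
            sep = filtering.min_pairwise_separation(models)
        else:
            sep = pd.Series(0.0, index=calls.index)
        calls = filtering.dedup_redundant(calls, sep, report)
        calls = filtering.filter_low_confidence(calls, confs, fcfg.conf_cutoff, report)
        model = filtering.segregation_model(self.config.sim.generations)
        calls = filtering.filter_segregation(calls, model, fcfg.alpha, report)
        calls = filtering.sample_qc(calls, fcfg.het_max, fcfg.hom_min, report=report)
        self._dedup_groups = report.dedup_groups
        io.write_genotypes(self.path("filtered_calls.tsv"), calls, meta)
        io.write_json(self.path("filter_report.json"), report.as_dict())
        pd.DataFrame(sorted(report.as_dict().items()),
                     columns=["rule", "n_removed"]).to_csv(
            self.path("filter_report.tsv"), sep="\t", index=False)
        for rule, n in sorted(report.as_dict().items()):
            log.info("filter %s: removed %d", rule, n)
        self._summary("filter", **report.as_dict(),
                      n_markers_out=len(calls), n_samples_out=calls.shape[1])
        return calls, report

    def stage_map(self):
        calls, meta = self._load_genotypes("filtered_calls.tsv")
        lmap = mapping.build_map(calls, self.config.map,
                                 getattr(self, "_dedup_groups", None))
        self._map = lmap
        markers = getattr(self, "_truth", None)
        io.write_map(self.path("map.tsv"),
                     lmap, markers.markers if markers is not None else None)
        self._summary("map", n_groups=len(lmap.linkage_groups),
                      n_mapped=len(lmap.table), n_unmapped=len(lmap.unmapped),
                      total_length_cm=lmap.total_length())
        return lmap

    def stage_refine(self):
        calls, meta = self._load_genotypes("filtered_calls.tsv")
        lmap = getattr(self, "_map", None)
        if lmap is None:
            lmap = io.read_map(self.path("map.tsv"))
        orders = {
            lg: list(lmap.table[lmap.table["linkage_group"] == lg]
                     .sort_values(["bin_index"], kind="stable").index)
            for lg in lmap.linkage_groups}
        orders = {lg: [m for m in o if m in calls.index] for lg, o in orders.items()}
        rcfg = self.config.refine
        refined = refine.refine_map_calls(calls, orders, rcfg.flank, rcfg.region_len)
        ncr = refine.nc_regions_per_sample(refined, orders)
        refined = filtering.sample_qc(
            refined, het_max=1.0, hom_min=0.0, nc_regions=ncr,
            max_nc_regions=self.config.filter.max_nc_regions)
        io.write_genotypes(self.path("refined_calls.tsv"), refined, meta)
        diff = refine.refinement_diff(calls[refined.columns], refined)
        diff.to_csv(self.path("refinement_diff.tsv"), sep="\t", index=False)
        self._summary("refine", n_changed=len(diff),
                      n_samples_out=refined.shape[1],
                      het_before=float((calls == "AB").to_numpy().mean()),
                      het_after=float((refined == "AB").to_numpy().mean()),
                      nc_before=float((calls == NC).to_numpy().mean()),
                      nc_after=float((refined == NC).to_numpy().mean()))
        return refined

    def stage_scan(self):
        refined, meta = self._load_genotypes("refined_calls.tsv")
        lmap = getattr(self, "_map", None)
        if lmap is None:
            lmap = io.read_map(self.path("map.tsv"))
        truth = getattr(self, "_truth", None)
        markers = truth.markers if truth is not None else meta
        scfg = self.config.scan
        table = lmap.table.loc[lmap.table.index.intersection(refined.index)]
        profile = scan.local_recomb_rate(table, markers["pos_mb"],
                                         span=scfg.lowess_span,
                                         window=scfg.slope_window)
        profile.table.to_csv(self.path("recomb_profile.tsv"), sep="\t", index=False,
                             float_format="%.5f")
        distortion = scan.segregation_scan(refined, markers, alpha=scfg.alpha,
                                           min_run=scfg.min_run)
        distortion.records.to_csv(self.path("distortion_records.tsv"), sep="\t",
                                  float_format="%.5g")
        distortion.intervals.to_csv(self.path("sdr_intervals.tsv"), sep="\t",
                                    index=False, float_format="%.4f")
        coll = scan.collinearity(table, markers)
        coll.to_csv(self.path("collinearity.tsv"), sep="\t", index=False,
                    float_format="%.4f")
        self._summary("scan", n_windows=len(profile.table),
                      n_sdr=len(distortion.intervals),
                      mean_r2=float(coll["r_squared"].mean()))
        return profile, distortion, coll


def run_pipeline(config: PipelineConfig, outdir, stages=None) -> Path:
    """Run the configured stages in order; returns the output directory.

    A stage failure raises with the stage name; artifacts written by earlier
    stages are left intact.
    """
    run = PipelineRun(config, outdir)
    todo = [s for s in STAGES if s in set(stages or config.stages)]
    for stage in todo:
        log.info("stage %s ...", stage)
        try:
            getattr(run, f"stage_{stage}")()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return run.outdir


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(outdir) -> dict:
    """Summary tables of a completed run (per-chromosome design stats and the
    map summary), written as TSV + Markdown; returns them as DataFrames."""
    outdir = Path(outdir)
    out = {}
    design_path = outdir / "probe_design.tsv"
    if design_path.exists():
        design = pd.read_csv(design_path, sep="\t")
        if len(design):
            snps = design.drop_duplicates("snp_id")
            per_chrom = snps.groupby("chrom").agg(
                n_snps=("snp_id", "count"),
                n_cds=("context", lambda s: int((s == "CDS").sum())),
                n_mrna=("context", lambda s: int((s == "mRNA").sum())),
                median_interval=("pos", lambda s: float(np.median(np.diff(np.sort(s))))
                                 if len(s) > 1 else np.nan),
            ).reset_index()
        else:
            per_chrom = pd.DataFrame(columns=["chrom", "n_snps", "n_cds", "n_mrna",
                                              "median_interval"])
        per_chrom.to_csv(outdir / "report_design.tsv", sep="\t", index=False)
        out["design"] = per_chrom
    map_path = outdir / "map.tsv"
    if map_path.exists():
        lmap = io.read_map(map_path)
        rows = []
        for lg in lmap.linkage_groups:
            sub = lmap.table[lmap.table["linkage_group"] == lg]
            bins = sub.groupby("bin_index")["cm"].first().sort_values()
            rows.append({
                "linkage_group": lg, "n_markers": len(sub), "n_bins": len(bins),
                "length_cm": float(bins.max()) if len(bins) else 0.0,
                "median_bin_interval_cm": float(np.median(np.diff(bins)))
                if len(bins) > 1 else np.nan,
                "median_markers_per_bin": float(sub.groupby("bin_index").size().median()),
            })
        map_summary = pd.DataFrame(rows)
        map_summary.to_csv(outdir / "report_map.tsv", sep="\t", index=False,
                           float_format="%.4f")
        out["map"] = map_summary
    lines = ["# Run report", ""]
    for name, df in out.items():
        lines.append(f"## {name}")
        lines.append("")
        lines.append("```")
        lines.append(df.to_string(index=False))
        lines.append("```")
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))
    return out
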