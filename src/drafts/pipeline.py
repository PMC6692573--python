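"""End-to-end pipeline: process -> quantify -> TSS -> features -> model -> compare.

Writes a manifest (package version, seed, input hashes, outputs) so a
rerun with the same manifest inputs reproduces byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List

import pandas as pd

import drafts
from drafts import quantify, tss_calling
from drafts.activity_model import cross_validate, fit_ols
from drafts.config import RunConfig
from drafts.cross_species import (
    hierarchical_cluster,
    pairwise_correlation,
    pca,
    profile_matrix,
    species_selective,
)
from drafts.library_io import load_library
from drafts.read_processing import AdaptorSpec, QcTally, process_fastq
from drafts.sequence_features import build_feature_matrix, discover_promoter_pwms


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all configured stages; returns the artifact directory.

    A stage failure aborts with the stage name; artifacts written by
    earlier stages are preserved.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "version": drafts.__version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "inputs": {},
        "outputs": [],
    }

    def emit(name: str) -> Path:
        manifest["outputs"].append(name)
        return outdir / name

    lib = load_library(cfg.library)
    manifest["inputs"][str(cfg.library)] = _sha256(Path(cfg.library))
    adaptor = AdaptorSpec(cfg.adaptor_seq, cfg.n_random_bases)

    # ---- process + count ------------------------------------------------
    stage = "process"
    try:
        tables: List[pd.DataFrame] = []
        pileup_store: Dict[str, tss_calling.TssPileup] = {}
        tallies: Dict[str, QcTally] = {}
        for sample, reps in cfg.samples.items():
            tally = QcTally()
            sample_reads = []
            for rep_id, kinds in reps.items():
                for kind_key, paths in kinds.items():
                    kind = kind_key.upper()
                    if isinstance(paths, (str, Path)):
                        paths = [paths]
                    manifest["inputs"][str(paths[0])] = _sha256(Path(paths[0]))
                    mate = paths[1] if len(paths) > 1 else None
                    if mate:
                        manifest["inputs"][str(mate)] = _sha256(Path(mate))
                    sample_reads.extend(
                        process_fastq(
                            lib,
                            paths[0],
                            kind,
                            rep_id,
                            adaptor=adaptor,
                            mate_path=mate,
                            min_overlap=cfg.min_overlap,
                            max_mismatch_frac=cfg.max_mismatch_frac,
                            adaptor_max_mismatches=cfg.adaptor_max_mismatches,
                            tally=tally,
                        )
                    )
            tally.assert_conserved()
            tallies[sample] = tally
            tables.append(
                quantify.tabulate_counts(
                    sample_reads, lib, sample=sample, counts_from=cfg.counts_from
                )
            )
            for cid, pile in tss_calling.build_pileups(sample_reads).items():
                store = pileup_store.setdefault(cid, tss_calling.TssPileup(cid))
                for pos, cnt in pile.positions.items():
                    store.add(pos, cnt)
        counts = quantify.merge_count_tables(tables)
        counts.to_csv(emit("counts.tsv"), sep="\t")
        with open(emit("qc.json"), "w") as fh:
            json.dump(
                {s: vars(t) | {"rejected": t.rejected} for s, t in tallies.items()},
                fh,
                indent=2,
                default=str,
            )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- quantify -------------------------------------------------------
    stage = "quantify"
    try:
        acts = quantify.compute_activity(
            counts, dna_min_reads=cfg.dna_min_reads, pseudocount=cfg.pseudocount
        )
        acts.to_csv(emit("activity.tsv"), sep="\t")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- TSS ------------------------------------------------------------
    stage = "tss"
    try:
        calls = tss_calling.call_all(
            pileup_store,
            k_seed=cfg.k_seed,
            merge_dist_bp=cfg.merge_dist_bp,
            min_frac=cfg.min_frac,
            primary_frac=cfg.primary_frac,
            primary_min_count=cfg.primary_min_count,
            secondary_frac=cfg.secondary_frac,
        )
        tss_calling.write_tss_tsv(calls, emit("tss.tsv"))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- features + model ----------------------------------------------
    stage = "features"
    model_sample = cfg.model_sample or next(iter(cfg.samples))
    fm = None
    try:
        pwms = discover_promoter_pwms(
            lib,
            acts,
            calls,
            sample=model_sample,
            top_frac=cfg.top_active_frac,
            width=cfg.motif_width,
            window=cfg.upstream_window,
            tss_region_bp=cfg.tss_region_bp,
        )
        for name, pwm in pwms.items():
            pwm.to_tsv(emit(f"pwm_{name}.tsv"))
        fm = build_feature_matrix(
            lib,
            acts,
            calls,
            pwms,
            sample=model_sample,
            optimal_spacer=cfg.optimal_spacer,
            max_dev=cfg.spacer_max_dev,
            window=cfg.upstream_window,
            tss_region_bp=cfg.tss_region_bp,
            fold_window_nt=cfg.fold_window_nt,
            fold_backend=cfg.fold_backend,
        )
        fm.features.to_csv(emit("features.tsv"), sep="\t")
        fm.correlations.to_csv(emit("feature_correlations.tsv"), sep="\t", header=["r"])
    except ValueError:
        fm = None  # too few annotated promoters; later stages skip the model

    stage = "model"
    try:
        if fm is not None and len(fm.features) >= 20:
            y = acts[(model_sample, "tx_z")].loc[fm.features.index]
            model = fit_ols(fm.features, y)
            rs = cross_validate(
                fm.features,
                y,
                train_frac=cfg.train_frac,
                repeats=cfg.cv_repeats,
                seed=cfg.seed,
            )
            model.r_test = float(pd.Series(rs).mean())
            model.train_fraction = cfg.train_frac
            model.to_json(emit("model.json"))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- compare --------------------------------------------------------
    stage = "compare"
    try:
        if len(cfg.samples) >= 2:
            m = profile_matrix(acts)
            if len(m) >= 3:
                pairwise_correlation(m).to_csv(emit("pairwise_r.tsv"), sep="\t")
                scores, evf = pca(m)
                scores.to_csv(emit("pca_scores.tsv"), sep="\t")
                pd.Series(
                    evf, index=scores.columns, name="explained_var_frac"
                ).to_csv(emit("pca_variance.tsv"), sep="\t")
                with open(emit("samples.nwk"), "w") as fh:
                    fh.write(hierarchical_cluster(m, axis="samples") + "\n")
            sel = species_selective(acts, fold=cfg.selective_fold)
            with open(emit("selective.json"), "w") as fh:
                json.dump(sel, fh, indent=2)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
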