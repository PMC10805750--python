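"""End-to-end pipeline driver: simulate → preprocess → train → generate → evaluate.

A single YAML/dict configuration describes every stage; each stochastic stage
receives a seed derived deterministically from the global seed and the stage
name, so a rerun with the same configuration reproduces identical artifacts.
The driver validates the configuration before any stage runs and writes a
manifest (file → SHA-256 checksum) of everything it produced.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np

from . import classifier as cl
from . import io as pio
from . import metrics as wm
from . import overlap as ov
from . import preprocess as pp
from . import signalsim as ss
from . import translator as tr

__all__ = ["DEFAULT_CONFIG", "validate_config", "stage_seed", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "pipeline_out",
    "simulate": {"n_records": 40, "af_fraction": 0.5, "duration_s": 60.0, "fs": 100.0},
    "preprocess": {"fs": 100.0, "qc_threshold": 0.96, "hr_floor": 30.0,
                   "segment_s": 30.0, "slice_s": 15.0, "stride_s": 1.0,
                   "compat": True},
    "train_gan": {"epochs": 4, "batch_size": 8, "lambda_rec": 100.0,
                  "crop_len": 1024, "depth": 4, "base_filters": 8, "kernel": 9},
    "evaluate": {"outlier_sd": 3.0},
    "embed": {"perplexity": 30.0, "iters": 300, "grid": 100, "max_per_population": 400},
    "train_clf": {"schemes": ["D1", "D2", "D4"], "epochs": 6, "batch": 64,
                  "n_boot": 200},
}


def validate_config(config: dict) -> dict:
    """Merge over defaults and validate; raises before any stage runs."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in (config or {}).items():
        if key not in cfg:
            raise ValueError(f"unknown config section {key!r}")
        if isinstance(val, dict):
            unknown = set(val) - set(cfg[key])
            if unknown:
                raise ValueError(f"unknown keys in {key!r}: {sorted(unknown)}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    sim, pre = cfg["simulate"], cfg["preprocess"]
    if not (0.0 <= sim["af_fraction"] <= 1.0):
        raise ValueError("simulate.af_fraction must lie in [0, 1]")
    if not (0.0 <= pre["qc_threshold"] <= 1.0):
        raise ValueError("preprocess.qc_threshold must lie in [0, 1]")
    if pre["stride_s"] <= 0 or pre["slice_s"] > pre["segment_s"]:
        raise ValueError("invalid slicing configuration")
    if cfg["train_gan"]["epochs"] < 0 or cfg["train_clf"]["epochs"] < 0:
        raise ValueError("epochs must be >= 0")
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed mixed with the stage name."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | None = None, log=print) -> dict:
    """Execute all stages in dependency order; returns the artifact manifest."""
    cfg = validate_config(config or {})
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "stages": {}, "files": {}}

    def done(stage: str, **info):
        manifest["stages"][stage] = {"status": "ok", **info}
        log(f"[{stage}] seed={stage_seed(cfg['seed'], stage)} {info}")

    try:
        # --- simulate ---
        sim = cfg["simulate"]
        seed = stage_seed(cfg["seed"], "simulate")
        records = ss.make_cohort(sim["n_records"], sim["af_fraction"],
                                 sim["duration_s"], seed=seed, fs=sim["fs"])
        rec_dir = out / "records"
        for rec in records:
            pio.write_record(rec, rec_dir)
        done("simulate", n_records=len(records))

        # --- preprocess ---
        pre = cfg["preprocess"]
        kept = [r for r in records
                if pp.qc_screen(r, pre["qc_threshold"], pre["hr_floor"]).passed]
        pairs, ppg_af, ppg_sr = [], [], []
        for rec in kept:
            rec = pp.resample(rec, pre["fs"])
            seg = pp.segment_annotated(rec, rec.rhythm_label, pre["segment_s"],
                                       channels="both")
            if len(seg):
                pairs.append(seg)
                ppg = pp.segment_annotated(rec, rec.rhythm_label, pre["segment_s"],
                                           channels="ppg")
                (ppg_af if rec.rhythm_label == "AF" else ppg_sr).append(ppg)
        pair_store = pp.SegmentStore.concat(pairs)
        pio.write_segments(pair_store, out / "pairs")
        done("preprocess", n_kept=len(kept), n_pairs=len(pair_store))

        # --- train-gan ---
        tg = cfg["train_gan"]
        gcfg = tr.TrainConfig(epochs=tg["epochs"], batch_size=tg["batch_size"],
                              lambda_rec=tg["lambda_rec"], crop_len=tg["crop_len"],
                              seed=stage_seed(cfg["seed"], "train_gan"))
        gspec = tr.GeneratorSpec(depth=tg["depth"], base_filters=tg["base_filters"],
                                 kernel=tg["kernel"])
        dspec = tr.DiscriminatorSpec(n_layers=max(2, tg["depth"] - 1),
                                     base_filters=tg["base_filters"], kernel=tg["kernel"])
        model = tr.gan_train(pair_store, gcfg, gspec, dspec)
        tr.save_model(model, out / "translator.npz")
        done("train_gan", final_mae=model.history["rec_mae"][-1])

        # --- generate ---
        ecg = pair_store.channel("ecg")
        gen = tr.generate_ppg(model, ecg)
        gen_store = pp.SegmentStore(gen, pair_store.labels,
                                    np.array(["generated"] * len(pair_store), dtype=object),
                                    pair_store.parent_id, pair_store.fs,
                                    pair_store.segment_seconds, ("ppg",))
        pio.write_segments(gen_store, out / "generated")
        done("generate", n_generated=len(gen_store))

        # --- evaluate ---
        ref = pair_store.channel("ppg")
        seg_metrics = [wm.SegmentMetric(prd=wm.prd(r, g), cc=wm.pearson_cc(r, g))
                       for r, g in zip(ref, gen)]
        report = wm.summarize(seg_metrics, outlier_sd=cfg["evaluate"]["outlier_sd"])
        (out / "metrics.json").write_text(json.dumps(report.__dict__, indent=2))
        done("evaluate", prd_mean=report.prd_mean, cc_mean=report.cc_mean)

        # --- embed ---
        emb_cfg = cfg["embed"]
        af_mask = pair_store.labels == "AF"
        real_af = pp.SegmentStore(ref[af_mask], pair_store.labels[af_mask],
                                  pair_store.origin[af_mask], pair_store.parent_id[af_mask],
                                  pair_store.fs, pair_store.segment_seconds, ("ppg",))
        gen_af = gen_store.subset(af_mask)
        result = ov.population_overlap(real_af, gen_af,
                                       perplexity=min(emb_cfg["perplexity"],
                                                      max(2, af_mask.sum() * 2 // 3)),
                                       iters=emb_cfg["iters"],
                                       seed=stage_seed(cfg["seed"], "embed"),
                                       resolution=emb_cfg["grid"],
                                       max_per_population=emb_cfg["max_per_population"])
        (out / "overlap.json").write_text(json.dumps({"do": result.do}, indent=2))
        done("embed", do=result.do)

        # --- train-clf ---
        tc = cfg["train_clf"]
        slicer = lambda store: pp.slice_segments(store, pre["slice_s"], pre["stride_s"],
                                                 pre["compat"])
        pools = {
            "generated_af": slicer(gen_af),
            "real_af": slicer(real_af),
            "real_sr": slicer(pp.SegmentStore.concat(ppg_sr)) if ppg_sr else None,
        }
        if pools["real_sr"] is None or len(pools["real_sr"]) == 0:
            done("train_clf", skipped="no SR records in cohort")
        else:
            # held-out test: split SR and AF pools group-wise
            rng = np.random.default_rng(stage_seed(cfg["seed"], "train_clf"))
            def split(store):
                parents = np.array(sorted(set(store.parent_id.tolist())))
                test_parents = set(rng.choice(parents, size=max(1, len(parents) // 4),
                                              replace=False).tolist())
                mask = np.isin(store.parent_id, list(test_parents))
                return store.subset(~mask), store.subset(mask)
            pools["real_af"], test_af = split(pools["real_af"])
            pools["real_sr"], test_sr = split(pools["real_sr"])
            pools["generated_af"] = pools["generated_af"].subset(
                ~np.isin(pools["generated_af"].parent_id, test_af.parent_id))
            test = pp.SegmentStore.concat([test_af, test_sr])
            table = cl.run_validation_experiment(pools, tc["schemes"], test,
                                                 epochs=tc["epochs"], batch=tc["batch"],
                                                 seed=stage_seed(cfg["seed"], "train_clf"),
                                                 n_boot=tc["n_boot"])
            table.to_csv(out / "classifier_table.csv", index=False)
            done("train_clf", schemes=tc["schemes"])
    except Exception as exc:  # manifest marks partial completion
        manifest["stages"]["error"] = {"status": "failed", "error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
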