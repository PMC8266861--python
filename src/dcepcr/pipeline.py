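"""End-to-end orchestration: simulate -> segment -> roi -> extract ->
select -> evaluate -> report.

Stages hand artifacts to each other through plain files (npz / CSV / JSON)
under one output directory, so every intermediate is inspectable. Each
stage writes a manifest (config echo, seed, input hashes, library
versions) sufficient to replay it; wall-clock timings go to a separate
log file so primary outputs stay deterministic.
"""

from __future__ import annotations

import copy
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._utils import dump_json, sha256_of_file, substream
from .clinical import associate, select_associated
from .evaluation import (ModelSpec, append_clinical, evaluate_loo,
                         independent_eval, loo_scores, subtype_stratified_eval,
                         youden_threshold)
from .features import FLAT_LEN, T1T2_LEN, extract_features, get_extractor
from .imaging import SegmentationError, box_to_mask, dice_coefficient, extract_roi
from .io import (load_feature_matrix, load_series_npz, save_feature_matrix,
                 save_series_npz)
from .selection import SelectionConfig, loo_dynamic_select
from .synthetic import (PhantomCohortConfig, SyntheticPhantomConfig,
                        gen_clinical_table, gen_phantom_cohort)

__all__ = ["DEFAULT_CONFIG", "PipelineError", "run_stage", "run_all", "STAGES"]

STAGES = ("simulate", "segment", "roi", "extract", "select", "evaluate", "report")

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {
        "fine_tuning": {"pcr": 30, "non_pcr": 78},
        "independent_test": {"pcr": 7, "non_pcr": 19},
        "volume_shape": [8, 48, 48],
        "assoc_strength": 1.0,
        "n_missing_her2": 2,
    },
    "segment": {"pe_threshold": 0.7, "ser_min": 0.9, "seed_pad": 4},
    "extract": {"backend": "filterbank", "subsample": 1000},
    "select": {"n_iterations": 20, "n_subsets": 10, "subset_fraction": 0.9,
               "alpha": 0.001, "variants": ["T1", "T2", "T1T2"]},
    "evaluate": {"kernel": "linear", "C": 1.0, "threshold_from": "test"},
}


class PipelineError(RuntimeError):
    pass


def merge_config(overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _versions() -> dict:
    import scipy
    import sklearn
    import skimage

    return {"dcepcr": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__, "scikit-image": skimage.__version__}


def _write_manifest(outdir: Path, stage: str, config: dict, inputs: list,
                    outputs: list, extra: dict | None = None) -> None:
    manifest = {
        "stage": stage,
        "seed": config["seed"],
        "config": config,
        "inputs": {str(Path(p).relative_to(outdir)): sha256_of_file(p) for p in inputs},
        "outputs": sorted(str(Path(p).relative_to(outdir)) for p in outputs),
        "versions": _versions(),
    }
    if extra:
        manifest.update(extra)
    dump_json(outdir / f"{stage}_manifest.json", manifest)


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing prerequisite artifact {path.name}: run stage "
            f"'{produced_by}' first")
    return path


def _log(outdir: Path, msg: str) -> None:
    with open(outdir / "pipeline.log", "a") as fh:
        fh.write(msg + "\n")


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------


def stage_simulate(config: dict, outdir: Path) -> list:
    sim = config["simulate"]
    n_pcr = sim["fine_tuning"]["pcr"] + sim["independent_test"]["pcr"]
    n_non = sim["fine_tuning"]["non_pcr"] + sim["independent_test"]["non_pcr"]
    shape = tuple(sim["volume_shape"])
    center = tuple(s // 2 for s in shape)
    # z-radius leaves headroom for the per-patient radius jitter
    radii = (max(1.5, shape[0] * 0.25), shape[1] * 0.2, shape[2] * 0.2)
    phantom = SyntheticPhantomConfig(volume_shape=shape, tumor_center=center,
                                     tumor_radii=radii)
    cohort = gen_phantom_cohort(PhantomCohortConfig(
        n_pcr=n_pcr, n_nonpcr=n_non, phantom=phantom, seed=config["seed"]))

    pdir = outdir / "patients"
    pdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    truth = {"patients": {}, "splits": {}}
    for rec in cohort:
        pid = rec["patient_id"]
        truth["patients"][pid] = {"label": rec["label"]}
        for tp in ("T1", "T2"):
            series, mask, ld = rec[tp]
            path = pdir / f"{pid}_{tp}.npz"
            save_series_npz(path, series, mask=mask, ld_mm=np.asarray(ld))
            truth["patients"][pid][f"ld_mm_{tp}"] = float(ld)
            outputs.append(path)

    # split: the first fine_tuning-count patients of each class, then test
    for cls, key in (("pcr", "pcr"), ("non", "non_pcr")):
        n_ft = sim["fine_tuning"][key]
        n_all = n_ft + sim["independent_test"][key]
        for i in range(n_all):
            truth["splits"][f"{cls}_{i:03d}"] = ("fine_tuning" if i < n_ft
                                                 else "independent_test")

    clinical = gen_clinical_table(n_pcr, n_non, assoc_strength=sim["assoc_strength"],
                                  seed=config["seed"],
                                  n_missing_her2=sim["n_missing_her2"])
    clinical["split"] = clinical["patient_id"].map(truth["splits"])
    clin_path = outdir / "clinical.csv"
    clinical.to_csv(clin_path, index=False)
    truth_path = outdir / "truth.json"
    dump_json(truth_path, truth)
    outputs += [clin_path, truth_path]
    _write_manifest(outdir, "simulate", config, [], outputs)
    return outputs


def _patient_order(truth: dict) -> list:
    return sorted(truth["patients"])


def stage_segment(config: dict, outdir: Path) -> list:
    truth = json.loads(_require(outdir / "truth.json", "simulate").read_text())
    seg = config["segment"]
    mdir = outdir / "masks"
    mdir.mkdir(exist_ok=True)
    outputs, inputs = [], [outdir / "truth.json"]
    provenance = {}
    for pid in _patient_order(truth):
        for tp in ("T1", "T2"):
            src = _require(outdir / "patients" / f"{pid}_{tp}.npz", "simulate")
            inputs.append(src)
            series, true_mask, _ = load_series_npz(src)
            # reader-supplied seed region: padded bounding box of the lesion
            nz = np.nonzero(true_mask)
            pad = seg["seed_pad"]
            box = tuple((max(int(a.min()) - pad, 0), min(int(a.max()) + 1 + pad, s))
                        for a, s in zip(nz, series.shape))
            mask = segment_case(series, box, seg, case_id=f"{pid}_{tp}")
            path = mdir / f"{pid}_{tp}.npz"
            np.savez_compressed(path, mask=mask)
            outputs.append(path)
            provenance[f"{pid}_{tp}"] = {
                "dice_vs_truth": round(dice_coefficient(mask, true_mask), 4),
                "n_voxels": int(mask.sum()),
            }
    prov_path = outdir / "segment_provenance.json"
    dump_json(prov_path, provenance)
    outputs.append(prov_path)
    _write_manifest(outdir, "segment", config, inputs, outputs)
    return outputs


def segment_case(series, box, seg_config: dict, case_id: str):
    from .imaging import segment_tumor

    seed_region = box_to_mask(series.shape, box)
    return segment_tumor(series, seed_region,
                         pe_threshold=seg_config["pe_threshold"],
                         ser_range=(seg_config["ser_min"], np.inf),
                         case_id=case_id)


def stage_roi(config: dict, outdir: Path) -> list:
    truth = json.loads(_require(outdir / "truth.json", "simulate").read_text())
    rdir = outdir / "rois"
    rdir.mkdir(exist_ok=True)
    outputs, inputs = [], [outdir / "truth.json"]
    provenance = {}
    for pid in _patient_order(truth):
        for tp in ("T1", "T2"):
            src = _require(outdir / "patients" / f"{pid}_{tp}.npz", "simulate")
            mask_path = _require(outdir / "masks" / f"{pid}_{tp}.npz", "segment")
            inputs += [src, mask_path]
            series, _, _ = load_series_npz(src)
            with np.load(mask_path) as z:
                mask = z["mask"].astype(bool)
            # the clinical-report LD drives the crop size
            ld = truth["patients"][pid][f"ld_mm_{tp}"]
            patch = extract_roi(series, mask, ld, timepoint=tp)
            path = rdir / f"{pid}_{tp}.npz"
            np.savez_compressed(path, image=patch.image)
            outputs.append(path)
            provenance[f"{pid}_{tp}"] = {
                "source_slice": patch.source_slice, "center": list(patch.center),
                "ld_mm": patch.ld_mm, "ld_px": patch.ld_px,
            }
    prov_path = outdir / "roi_provenance.json"
    dump_json(prov_path, provenance)
    outputs.append(prov_path)
    _write_manifest(outdir, "roi", config, inputs, outputs)
    return outputs


def stage_extract(config: dict, outdir: Path) -> list:
    truth = json.loads(_require(outdir / "truth.json", "simulate").read_text())
    ext = config["extract"]
    extractor = get_extractor(ext["backend"], seed=config["seed"])
    pids = _patient_order(truth)
    rows = []
    inputs = [outdir / "truth.json"]
    for pid in pids:
        vecs = []
        for tp in ("T1", "T2"):
            src = _require(outdir / "rois" / f"{pid}_{tp}.npz", "roi")
            inputs.append(src)
            with np.load(src) as z:
                img = z["image"]
            from .imaging import RoiPatch

            patch = RoiPatch(image=img, source_slice=0, center=(0, 0),
                             ld_mm=1.0, ld_px=8, timepoint=tp)
            vecs.append(extract_features(patch, extractor, patient_id=pid).values)
        rows.append(np.concatenate(vecs))
    matrix = np.asarray(rows)

    subsample = ext.get("subsample")
    if subsample and subsample < T1T2_LEN:
        rng = substream(config["seed"], 23)
        keep = np.sort(rng.choice(T1T2_LEN, size=int(subsample), replace=False))
    else:
        keep = np.arange(T1T2_LEN)
    matrix = matrix[:, keep]
    written = save_feature_matrix(outdir / "features_T1T2", matrix, pids, keep)
    sidecar = outdir / "features_sidecar.json"
    dump_json(sidecar, {"backend": extractor.name, "extractor_seed": config["seed"],
                        "normalization": "per-patch min-max to [0,1]",
                        "n_features_total": T1T2_LEN,
                        "kept_global_indices": keep})
    outputs = [Path(p) for p in written.values()] + [sidecar]
    _write_manifest(outdir, "extract", config, inputs, outputs)
    return outputs


def _load_cohort(outdir: Path):
    truth = json.loads(_require(outdir / "truth.json", "simulate").read_text())
    matrix, pids, feat_ids = load_feature_matrix(
        _require(outdir / "features_T1T2.npz", "extract").with_suffix(""))
    labels = np.array([truth["patients"][p]["label"] for p in pids])
    split = np.array([truth["splits"][p] for p in pids])
    clinical = pd.read_csv(outdir / "clinical.csv")
    clinical = clinical.set_index("patient_id").loc[pids].reset_index()
    return matrix, np.asarray(feat_ids), labels, split, clinical, pids


def stage_select(config: dict, outdir: Path) -> list:
    matrix, feat_ids, labels, split, _, _ = _load_cohort(outdir)
    sel = config["select"]
    ft = split == "fine_tuning"
    X, y = matrix[ft], labels[ft]
    cfg = SelectionConfig(n_iterations=sel["n_iterations"], n_subsets=sel["n_subsets"],
                          subset_fraction=sel["subset_fraction"], alpha=sel["alpha"],
                          seed=config["seed"])
    outputs = []
    for variant in sel["variants"]:
        if variant == "T1":
            cols = np.flatnonzero(feat_ids < FLAT_LEN)
        elif variant == "T2":
            cols = np.flatnonzero(feat_ids >= FLAT_LEN)
        else:
            cols = np.arange(len(feat_ids))
        result = loo_dynamic_select(X[:, cols], y, cfg)
        payload = result.to_dict()
        payload["variant"] = variant
        payload["columns_are_indices_into"] = "features_T1T2 columns"
        payload["local_to_matrix_columns"] = cols[sorted(result.osf)].tolist()
        payload["osf_global_feature_ids"] = feat_ids[cols[sorted(result.osf)]].tolist()
        path = outdir / f"selection_{variant}.json"
        dump_json(path, payload)
        # plain-text index list for downstream tooling
        txt = outdir / f"osf_{variant}.txt"
        txt.write_text("\n".join(map(str, payload["osf_global_feature_ids"])) + "\n")
        outputs += [path, txt]
    _write_manifest(outdir, "select", config, [outdir / "features_T1T2.npz"], outputs,
                    extra={"draw_digest": result.draw_digest})
    return outputs


def _osf_matrix_cols(outdir: Path, variant: str) -> np.ndarray:
    path = _require(outdir / f"selection_{variant}.json", "select")
    payload = json.loads(path.read_text())
    return np.asarray(payload["local_to_matrix_columns"], int)


def stage_evaluate(config: dict, outdir: Path) -> list:
    matrix, feat_ids, labels, split, clinical, _ = _load_cohort(outdir)
    ev = config["evaluate"]
    sel_variants = config["select"]["variants"]
    ft = split == "fine_tuning"
    te = split == "independent_test"
    spec = ModelSpec(kernel=ev["kernel"], C=ev["C"], seed=config["seed"])

    assoc = associate(clinical[ft].reset_index(drop=True))
    integrate = [v for v in select_associated(assoc)
                 if v in ("er", "pgr", "her2", "subtype")]
    edir = outdir / "eval"
    edir.mkdir(exist_ok=True)
    outputs = []
    results = {}

    def record(name, report):
        results[name] = report
        path = edir / f"{name}.json"
        dump_json(path, report.to_dict())
        roc_path = edir / f"roc_{name}.csv"
        report.roc.to_csv(roc_path, index=False)
        outputs.extend([path, roc_path])

    def clin_subset(mask):
        return clinical.loc[mask, ["er", "pgr", "her2", "subtype"]].reset_index(drop=True)

    skipped = {}
    for variant in sel_variants:
        cols = _osf_matrix_cols(outdir, variant)
        if len(cols) == 0:
            skipped[f"osf_{variant}"] = ("empty OSF: rerun selection with a larger "
                                         "alpha or stronger class effect")
            continue
        Xv = matrix[:, cols]
        record(f"loo_osf_{variant}", evaluate_loo(Xv[ft], labels[ft], spec=spec))
        if integrate:
            record(f"loo_osf_{variant}_clinical",
                   evaluate_loo(Xv[ft], labels[ft], clinical=clin_subset(ft), spec=spec))

    if integrate:
        empty = np.empty((int(ft.sum()), 0))
        record("loo_clinical", evaluate_loo(empty, labels[ft],
                                            clinical=clin_subset(ft), spec=spec))

    # independent test on the best variant (T1T2 when available)
    best = "T1T2" if "T1T2" in sel_variants else sel_variants[-1]
    cols = _osf_matrix_cols(outdir, best)
    if len(cols):
        Xv = matrix[:, cols]
        record(f"test_osf_{best}",
               independent_eval(Xv[ft], labels[ft], Xv[te], labels[te], spec=spec,
                                threshold_from=ev["threshold_from"]))
        if integrate:
            record(f"test_osf_{best}_clinical",
                   independent_eval(Xv[ft], labels[ft], Xv[te], labels[te],
                                    clinical_train=clin_subset(ft),
                                    clinical_test=clin_subset(te), spec=spec,
                                    threshold_from=ev["threshold_from"]))
        # subtype-stratified LOO metrics for the best model
        rep = results[f"loo_osf_{best}"]
        strat = subtype_stratified_eval(rep.scores, labels[ft],
                                        clinical.loc[ft, "subtype"].to_numpy(),
                                        rep.youden_threshold)
        strat_path = edir / f"subtype_stratified_{best}.json"
        dump_json(strat_path, strat)
        outputs.append(strat_path)
    if integrate:
        empty_tr = np.empty((int(ft.sum()), 0))
        empty_te = np.empty((int(te.sum()), 0))
        record("test_clinical",
               independent_eval(empty_tr, labels[ft], empty_te, labels[te],
                                clinical_train=clin_subset(ft),
                                clinical_test=clin_subset(te), spec=spec,
                                threshold_from=ev["threshold_from"]))

    assoc_path = edir / "clinical_association.json"
    dump_json(assoc_path, {"report": assoc.to_dict(), "integrated": integrate})
    outputs.append(assoc_path)
    _write_manifest(outdir, "evaluate", config,
                    [outdir / "features_T1T2.npz", outdir / "clinical.csv"],
                    outputs, extra={"skipped": skipped})
    return outputs


def stage_report(config: dict, outdir: Path) -> list:
    edir = _require(outdir / "eval", "evaluate")
    rows = []
    for path in sorted(edir.glob("*.json")):
        if path.name.startswith(("roc_", "subtype_", "clinical_")):
            continue
        d = json.loads(path.read_text())
        if "auc" not in d:
            continue
        name = path.stem
        n_feat = len(d["scores"])
        rows.append({
            "model": name,
            "set": "independent_test" if name.startswith("test_") else "fine_tuning",
            "n_patients": d["n_pos"] + d["n_neg"],
            "accuracy_pct": d["accuracy"],
            "sensitivity_pct": d["sensitivity"],
            "specificity_pct": d["specificity"],
            "auc": round(d["auc"], 3),
        })
    summary = pd.DataFrame(rows).sort_values(["set", "model"]).reset_index(drop=True)
    csv_path = outdir / "summary.csv"
    summary.to_csv(csv_path, index=False)
    md_path = outdir / "summary.md"
    md_path.write_text(summary.to_markdown(index=False) + "\n")
    _write_manifest(outdir, "report", config, [], [csv_path, md_path])
    return [csv_path, md_path]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "roi": stage_roi,
    "extract": stage_extract,
    "select": stage_select,
    "evaluate": stage_evaluate,
    "report": stage_report,
}


def run_stage(stage: str, config: dict | None = None, outdir=".") -> list:
    """Run one pipeline stage (or ``"all"``) under ``outdir``."""
    cfg = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stage == "all":
        return run_all(cfg, outdir)
    if stage not in _STAGE_FUNCS:
        raise PipelineError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    t0 = time.perf_counter()
    out = _STAGE_FUNCS[stage](cfg, outdir)
    _log(outdir, f"stage {stage}: {time.perf_counter() - t0:.2f}s, "
                 f"{len(out)} artifacts")
    return out


def run_all(config: dict | None = None, outdir=".") -> list:
    cfg = merge_config(config)
    outputs = []
    for stage in STAGES:
        outputs += run_stage(stage, cfg, outdir)
    return outputs
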