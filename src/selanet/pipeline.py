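"""End-to-end orchestration: synth -> preprocess -> train-ae -> encode ->
train-sel -> evaluate, with on-disk artifacts between stages.

Artifacts live under one output root::

    root/records/S000.npz + .json      generator output (or imported records)
    root/segments/segments.npz         stacked windows per split + manifest.csv
    root/models/ae.npz + ae.json       autoencoder checkpoint
    root/segments/latents.npz          encoded features per split
    root/models/sel_cXX.npz + .json    selective checkpoints per coverage
    root/reports/eval_cXX.json         evaluation reports

Each artifact records a hash of the configuration that produced its inputs;
downstream stages refuse to mix artifacts with mismatched hashes.  All
randomness descends from one master seed (stage seeds are spawned from it in
a fixed order), so re-running with an unchanged config reproduces artifacts
bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .autoencoder import TCNAutoencoder
from .evaluate import EvalReport, evaluate_model
from .preprocess import preprocess_record, split_and_balance
from .records import Segment, SegmentSet, SignalRecord
from .selective import SelectiveClassifier
from .synthgen import SynthConfig, generate_cohort

log = logging.getLogger("selanet")

STAGES = ("synth", "preprocess", "train-ae", "encode", "train-sel", "evaluate")


@dataclass
class PipelineConfig:
    """Everything one run needs; absent YAML fields take these defaults."""

    out_dir: str = "selanet_run"
    seed: int = 0
    # cohort
    n_subjects: int = 20
    synth: SynthConfig = field(default_factory=SynthConfig)
    # preprocessing
    window_s: float = 30.0
    overlap_s: float = 5.0
    split_fractions: tuple[float, float, float] = (0.70, 0.05, 0.25)
    # autoencoder (desk-scale defaults; the full-scale setting is epochs=100)
    ae_epochs: int = 40
    ae_batch_size: int = 32
    ae_lr: float = 1e-3
    ae_patience: int = 5
    ae_max_train_segments: int = 512
    # selective training
    coverages: tuple[float, ...] = (0.90, 0.95, 0.98)
    sel_epochs: int = 50
    sel_lam: float = 200.0
    sel_alpha: float = 0.3
    sel_lr: float = 1e-3
    sel_batch_size: int = 64
    sel_lr_patience: int = 10
    # evaluation
    eval_block_size: int = 64

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("split_fractions", "coverages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synth=synth, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    # -- seeds: fixed spawn order keeps stages independent and reproducible
    def stage_seed(self, stage: str) -> int:
        order = {"synth": 0, "split": 1, "ae": 2, "sel": 3, "eval": 4}
        child = np.random.SeedSequence(self.seed).spawn(5)[order[stage]]
        return int(child.generate_state(1)[0] % (2**31))

    def preprocessing_hash(self) -> str:
        payload = {"synth": asdict(self.synth), "n_subjects": self.n_subjects,
                   "window_s": self.window_s, "overlap_s": self.overlap_s,
                   "split_fractions": list(self.split_fractions),
                   "seed": self.seed}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# segment store
# ---------------------------------------------------------------------------

def save_segment_store(sets: dict[str, SegmentSet], directory: Path,
                       config_hash: str) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    rows = []
    for split, sset in sets.items():
        arrays[f"x_{split}"] = sset.stacked_x()
        for s in sset.segments:
            rows.append({"split": split, "subject_id": s.subject_id,
                         "start_s": s.start_s, "y": s.y if s.y else "",
                         "ambiguous_tag": s.ambiguous_tag})
    np.savez_compressed(directory / "segments.npz", **arrays)
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    (directory / "store.json").write_text(json.dumps(
        {"config_hash": config_hash,
         "splits": {k: len(v.segments) for k, v in sets.items()}}, indent=1))


def load_segment_store(directory: Path) -> tuple[dict[str, SegmentSet], str]:
    manifest = pd.read_csv(directory / "manifest.csv",
                           keep_default_na=False)
    meta = json.loads((directory / "store.json").read_text())
    sets: dict[str, SegmentSet] = {}
    with np.load(directory / "segments.npz") as z:
        for split in manifest["split"].unique():
            sub = manifest[manifest["split"] == split].reset_index(drop=True)
            X = z[f"x_{split}"]
            segs = [Segment(subject_id=row.subject_id, start_s=row.start_s,
                            x=X[i], y=(row.y or None),
                            ambiguous_tag=bool(row.ambiguous_tag))
                    for i, row in sub.iterrows()]
            sets[split] = SegmentSet(segments=segs, split=split)
    return sets, meta["config_hash"]


def _check_hash(expected: str, found: str, what: str) -> None:
    if expected != found:
        raise RuntimeError(f"{what} was produced under config hash {found}, "
                           f"current config hashes to {expected}; regenerate "
                           "upstream artifacts")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_log(stage: str, t0: float, **info) -> None:
    kv = " ".join(f"{k}={v}" for k, v in info.items())
    log.info("stage=%s wall_s=%.1f %s", stage, time.time() - t0, kv)


def run_synth(cfg: PipelineConfig) -> list[SignalRecord]:
    t0 = time.time()
    records = generate_cohort(cfg.n_subjects, cfg.synth,
                              seed=cfg.stage_seed("synth"))
    rec_dir = Path(cfg.out_dir) / "records"
    for rec in records:
        rec.save(rec_dir)
    _stage_log("synth", t0, subjects=len(records))
    return records


def run_preprocess(cfg: PipelineConfig) -> dict[str, SegmentSet]:
    t0 = time.time()
    rec_dir = Path(cfg.out_dir) / "records"
    paths = sorted(rec_dir.glob("*.npz"))
    if not paths:
        raise RuntimeError("missing stage 'synth': no records found under "
                           f"{rec_dir}")
    segments: list[Segment] = []
    for p in paths:
        rec = SignalRecord.load(p)
        segments.extend(preprocess_record(rec, window_s=cfg.window_s,
                                          overlap_s=cfg.overlap_s))
    sets = split_and_balance(segments, fractions=cfg.split_fractions,
                             seed=cfg.stage_seed("split"))
    save_segment_store(sets, Path(cfg.out_dir) / "segments",
                       cfg.preprocessing_hash())
    _stage_log("preprocess", t0,
               **{k: len(v.segments) for k, v in sets.items()})
    return sets


def run_train_ae(cfg: PipelineConfig) -> TCNAutoencoder:
    t0 = time.time()
    seg_dir = Path(cfg.out_dir) / "segments"
    if not (seg_dir / "segments.npz").exists():
        raise RuntimeError("missing stage 'preprocess': no segment store")
    sets, found = load_segment_store(seg_dir)
    _check_hash(cfg.preprocessing_hash(), found, "segment store")
    rng = np.random.default_rng(cfg.stage_seed("ae"))
    X_train = sets["train"].stacked_x()
    if len(X_train) > cfg.ae_max_train_segments:
        pick = rng.choice(len(X_train), cfg.ae_max_train_segments, replace=False)
        X_train = X_train[np.sort(pick)]
    X_val = sets["val"].stacked_x()
    ae = TCNAutoencoder(epochs=cfg.ae_epochs, batch_size=cfg.ae_batch_size,
                        lr=cfg.ae_lr, patience=cfg.ae_patience,
                        random_state=cfg.stage_seed("ae"))
    ae.fit(X_train, X_val=X_val if len(X_val) else None)
    model_dir = Path(cfg.out_dir) / "models"
    model_dir.mkdir(parents=True, exist_ok=True)
    ae.save(model_dir / "ae.npz")
    (model_dir / "ae.meta.json").write_text(json.dumps(
        {"config_hash": cfg.preprocessing_hash(),
         "epochs_run": ae.n_epochs_,
         "best_val_mse": ae.best_val_mse_}, indent=1))
    _stage_log("train-ae", t0, epochs=ae.n_epochs_,
               val_mse=round(ae.history_["val_mse"].min(), 6))
    return ae


def run_encode(cfg: PipelineConfig) -> dict[str, np.ndarray]:
    t0 = time.time()
    seg_dir = Path(cfg.out_dir) / "segments"
    model_dir = Path(cfg.out_dir) / "models"
    if not (model_dir / "ae.npz").exists():
        raise RuntimeError("missing stage 'train-ae': no autoencoder checkpoint")
    sets, found = load_segment_store(seg_dir)
    _check_hash(cfg.preprocessing_hash(), found, "segment store")
    ae = TCNAutoencoder.load(model_dir / "ae.npz")
    arrays: dict[str, np.ndarray] = {}
    for split, sset in sets.items():
        X = sset.stacked_x()
        if len(X):
            arrays[f"z_{split}"] = ae.transform(X).astype(np.float32)
            arrays[f"y_{split}"] = np.array(
                ["ambiguous" if s.ambiguous_tag else s.y
                 for s in sset.segments], dtype="U16")
            arrays[f"subj_{split}"] = np.array(
                [s.subject_id for s in sset.segments], dtype="U16")
    np.savez_compressed(seg_dir / "latents.npz", **arrays)
    (seg_dir / "latents.json").write_text(json.dumps(
        {"config_hash": cfg.preprocessing_hash()}, indent=1))
    _stage_log("encode", t0, splits=len([k for k in arrays if k.startswith("z_")]))
    return arrays


def _load_latents(cfg: PipelineConfig) -> dict[str, np.ndarray]:
    seg_dir = Path(cfg.out_dir) / "segments"
    if not (seg_dir / "latents.npz").exists():
        raise RuntimeError("missing stage 'encode': no latent store")
    meta = json.loads((seg_dir / "latents.json").read_text())
    _check_hash(cfg.preprocessing_hash(), meta["config_hash"], "latent store")
    with np.load(seg_dir / "latents.npz") as z:
        return {k: z[k] for k in z.files}


def run_train_sel(cfg: PipelineConfig) -> dict[float, SelectiveClassifier]:
    t0 = time.time()
    lat = _load_latents(cfg)
    model_dir = Path(cfg.out_dir) / "models"
    model_dir.mkdir(parents=True, exist_ok=True)
    models = {}
    for i, c in enumerate(cfg.coverages):
        clf = SelectiveClassifier(
            target_coverage=c, lam=cfg.sel_lam, alpha=cfg.sel_alpha,
            lr=cfg.sel_lr, batch_size=cfg.sel_batch_size,
            epochs=cfg.sel_epochs, lr_patience=cfg.sel_lr_patience,
            random_state=cfg.stage_seed("sel") + i)
        clf.fit(lat["z_train"], lat["y_train"],
                Z_val=lat.get("z_val"), y_val=lat.get("y_val"))
        tag = f"c{int(round(c * 100)):02d}"
        clf.save(model_dir / f"sel_{tag}.npz")
        clf.history_.to_csv(model_dir / f"sel_{tag}_history.csv", index=False)
        models[c] = clf
        _stage_log("train-sel", t0, coverage=c,
                   final_phi=round(clf.history_["coverage"].iloc[-1], 4))
    return models


def run_evaluate(cfg: PipelineConfig) -> dict[float, EvalReport]:
    t0 = time.time()
    lat = _load_latents(cfg)
    model_dir = Path(cfg.out_dir) / "models"
    report_dir = Path(cfg.out_dir) / "reports"
    report_dir.mkdir(parents=True, exist_ok=True)
    reports = {}
    for c in cfg.coverages:
        tag = f"c{int(round(c * 100)):02d}"
        ckpt = model_dir / f"sel_{tag}.npz"
        if not ckpt.exists():
            raise RuntimeError(f"missing stage 'train-sel': no checkpoint {ckpt}")
        clf = SelectiveClassifier.load(ckpt)
        rep = evaluate_model(clf, lat["z_test"], lat["y_test"],
                             Z_ambiguous=lat.get("z_ambiguous"),
                             block_size=cfg.eval_block_size)
        rep.save(report_dir / f"eval_{tag}.json")
        reports[c] = rep
        _stage_log("evaluate", t0, coverage=c,
                   violation=round(rep.coverage_violation, 4),
                   selected_acc=round(rep.selected["accuracy"], 4))
    return reports


_RUNNERS = {"synth": run_synth, "preprocess": run_preprocess,
            "train-ae": run_train_ae, "encode": run_encode,
            "train-sel": run_train_sel, "evaluate": run_evaluate}


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in canonical order; each stage reads its
    inputs from disk, so any prefix can be re-run or resumed."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(Path(cfg.out_dir) / "config.yaml")
    results = {}
    for stage in STAGES:
        if stage in stages:
            results[stage] = _RUNNERS[stage](cfg)
    return results


def ablation_channel_mask(X: np.ndarray, keep: str) -> np.ndarray:
    """Zero one channel for single-modality ablation ('edr' or 'sao2')."""
    Xm = np.array(X, copy=True)
    if keep == "edr":
        Xm[:, 1, :] = 0.5
    elif keep == "sao2":
        Xm[:, 0, :] = 0.5
    else:
        raise ValueError("keep must be 'edr' or 'sao2'")
    return Xm
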