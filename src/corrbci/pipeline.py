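"""End-to-end orchestration: simulate/load -> preprocess -> select ->
features -> classify, with all intermediate artifacts written as plain text
and a manifest (content hashes, seeds, config hash) for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify as cl
from . import features as ft
from . import selection as sel
from .io import EventTable, Recording, write_events, write_recording
from .preprocessing import EEG_FILTER, FNIRS_FILTER, FilterSpec, MbllParams, \
    preprocess_eeg, preprocess_fnirs
from .synthetic import SyntheticConfig, generate_session

log = logging.getLogger("corrbci")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    eeg_filter: FilterSpec = EEG_FILTER
    fnirs_filter: FilterSpec = FNIRS_FILTER
    mbll: MbllParams = field(default_factory=MbllParams)
    window_s: float = 0.096
    zero_phase: bool = True
    k_eeg: dict[str, int] = field(default_factory=lambda: {"left": 3, "right": 3})
    k_fnirs: dict[str, int] = field(default_factory=lambda: {"left": 5, "right": 5})
    score: str = "abs"                       # channel score: abs | signed
    averaging: str = "hemisphere"            # hemisphere | pooled
    classifiers: tuple[cl.ClassifierSpec, ...] = cl.DEFAULT_SPECS
    folds: int = 10
    cv_seed: int = 0
    modes: tuple[str, ...] = ("eeg", "fnirs", "hybrid")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw: dict = {}
        if "synthetic" in d:
            kw["synthetic"] = SyntheticConfig(**d["synthetic"])
        if "eeg_filter" in d:
            kw["eeg_filter"] = FilterSpec(**d["eeg_filter"])
        if "fnirs_filter" in d:
            kw["fnirs_filter"] = FilterSpec(**d["fnirs_filter"])
        if "mbll" in d:
            kw["mbll"] = MbllParams(**d["mbll"])
        if "classifiers" in d:
            kw["classifiers"] = tuple(
                cl.ClassifierSpec.make(c.pop("algorithm"), **c)
                for c in [dict(c) for c in d["classifiers"]])
        for key in ("window_s", "zero_phase", "k_eeg", "k_fnirs", "score",
                    "averaging", "folds", "cv_seed"):
            if key in d:
                kw[key] = d[key]
        if "modes" in d:
            kw["modes"] = tuple(d["modes"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {f.name: enc(getattr(o, f.name))
                        for f in dataclasses.fields(o)}
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (tuple, list)):
                return [enc(v) for v in o]
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            return o
        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, t0: float, **info) -> None:
    log.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0,
             " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None,
                 eeg: Recording | None = None, fnirs_od: Recording | None = None,
                 events: EventTable | None = None) -> dict:
    """Run the full chain; simulate a session unless recordings are given.

    Returns the run report (selected channels, accuracy grids, best cells);
    when ``out_dir`` is set, also writes every intermediate artifact plus
    ``manifest.json`` with content hashes.
    """
    t0 = time.perf_counter()
    written: list[Path] = []
    out = Path(out_dir) if out_dir is not None else None

    if eeg is None or fnirs_od is None or events is None:
        eeg, fnirs_od, events, truth = generate_session(config.synthetic)
        _stage("simulate", t0, eeg=eeg.data.shape, fnirs=fnirs_od.data.shape,
               trials=len(events))
        if out is not None:
            written += write_recording(eeg, out, "eeg_raw")
            written += write_recording(fnirs_od, out, "fnirs_od")
            written.append(write_events(events, out / "events.tsv"))
    else:
        truth = None

    eeg_p = preprocess_eeg(eeg, config.eeg_filter, config.window_s,
                           zero_phase=config.zero_phase)
    fnirs_p = preprocess_fnirs(fnirs_od, config.fnirs_filter, config.mbll,
                               config.window_s, zero_phase=config.zero_phase)
    _stage("preprocess", t0, eeg=eeg_p.data.shape, eeg_fs=round(eeg_p.fs, 3),
           fnirs=fnirs_p.data.shape)
    if out is not None:
        written += write_recording(eeg_p, out, "eeg_preprocessed")
        written += write_recording(fnirs_p, out, "fnirs_hbo_preprocessed")

    report: dict = {"config_hash": config.config_hash(),
                    "n_trials": len(events), "selected": {}, "grids": {}}
    selected: dict[str, list[str]] = {}
    for name, rec, kmap in (("eeg", eeg_p, config.k_eeg),
                            ("fnirs", fnirs_p, config.k_fnirs)):
        for hemi, k in kmap.items():
            if k > len(rec.hemisphere_channels(hemi)):
                raise ValueError(
                    f"selection stage: k_{name}[{hemi}]={k} exceeds the "
                    f"{len(rec.hemisphere_channels(hemi))}-channel group")
        rankings = sel.rank_hemispheres(rec, events, score=config.score)
        selected[name] = (rankings["left"].top(kmap["left"])
                          + rankings["right"].top(kmap["right"]))
        report["selected"][name] = selected[name]
        if out is not None:
            rep = sel.ranking_report(rankings, kmap)
            path = out / f"{name}_channel_report.tsv"
            rep.to_csv(path, sep="\t", index=False)
            written.append(path)
    _stage("select", t0, eeg=selected["eeg"], fnirs=selected["fnirs"])

    eeg_feats = ft.extract_features(eeg_p, events, selected["eeg"], "eeg",
                                    scheme=config.averaging)
    fnirs_feats = ft.extract_features(fnirs_p, events, selected["fnirs"],
                                      "fnirs", scheme=config.averaging)
    if out is not None:
        for name, feats in (("eeg", eeg_feats), ("fnirs", fnirs_feats)):
            path = out / f"{name}_features.tsv"
            feats.to_csv(path, sep="\t", index=False)
            written.append(path)
    _stage("features", t0, eeg_cols=eeg_feats.shape[1],
           fnirs_cols=fnirs_feats.shape[1])

    for mode in config.modes:
        sets = ft.build_feature_sets(eeg=eeg_feats, fnirs=fnirs_feats, mode=mode)
        grid_res = cl.evaluate_grid(sets, config.classifiers, k=config.folds,
                                    seed=config.cv_seed)
        best_set, best_algo, best_acc = grid_res.best
        report["grids"][mode] = {
            "accuracy": {sid: {a: float(grid_res.grid.loc[sid, a])
                               for a in grid_res.grid.columns}
                         for sid in grid_res.grid.index},
            "best": {"feature_set": best_set, "classifier": best_algo,
                     "mean_accuracy": best_acc},
        }
        if out is not None:
            path = out / f"grid_{mode}.tsv"
            grid_res.grid.to_csv(path, sep="\t", index_label="feature_set")
            written.append(path)
        _stage(f"classify[{mode}]", t0, sets=len(sets),
               best=f"{best_set}/{best_algo}={best_acc:.1f}%")

    if truth is not None:
        report["ground_truth"] = {"planted_eeg": truth.planted_eeg,
                                  "planted_fnirs": truth.planted_fnirs}

    if out is not None:
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=2))
        written.append(report_path)
        manifest = {
            "config_hash": config.config_hash(),
            "seeds": {"synthetic": config.synthetic.seed, "cv": config.cv_seed},
            "files": {p.name: _sha256(p) for p in written},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
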