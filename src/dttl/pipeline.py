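"""End-to-end orchestration of the translation-transfer training loop.

One outer iteration runs: adversarial adaptation (CDA) -> target
pseudo-labeling/partition -> minority translation (CMT) -> synthesis ->
confidence-based selection -> balanced-set assembly -> balanced target
learning (BTL), then evaluates the final classifier on a stratified
held-out slice of the target domain whose hidden labels are used *only*
for splitting and evaluation.

Ablation entry points mirror the component-removal experiments: the
no-adaptation variant replaces the adversarial stage with source-only
supervised training, and the no-translation variant trains the balanced
stage directly on the raw pseudo-labeled partition.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import btl as btl_mod
from . import cda as cda_mod
from . import cmt as cmt_mod
from .config import RunConfig, config_hash
from .data import CLASS_NAMES, MIN, MAJ, CohortPair, LabeledImages, load_image_dataset
from .metrics import EvalReport, evaluate
from .synthetic import make_cohort

__all__ = ["RunReport", "run_dttl", "run_ablation", "run_source_only",
           "stratified_target_split", "load_image_dataset"]


@dataclass
class RunReport:
    eval: EvalReport
    config_hash: str
    seed: int
    ablation_flags: tuple[str, ...] = ()
    n_synthesized: int = 0
    n_selected: int = 0
    stage_artifacts: dict[str, str] = field(default_factory=dict)


def _stage_seeds(seed: int) -> dict[str, int]:
    words = np.random.SeedSequence(seed).generate_state(5, dtype=np.uint32)
    names = ("cohort", "split", "cda", "cmt", "btl")
    return {k: int(w & 0x7FFFFFFF) for k, w in zip(names, words)}


def stratified_target_split(hidden_labels: np.ndarray, eval_frac: float,
                            seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split of target indices into (train, eval).

    Uses the hidden labels for stratification only; when labels are
    unavailable (all -1) the split is a plain random one.
    """
    rng = np.random.default_rng(seed)
    hidden = np.asarray(hidden_labels)
    train_idx, eval_idx = [], []
    classes = np.unique(hidden)
    for cls in classes:
        idx = np.flatnonzero(hidden == cls)
        idx = idx[rng.permutation(len(idx))]
        n_eval = int(round(eval_frac * len(idx)))
        eval_idx.append(idx[:n_eval])
        train_idx.append(idx[n_eval:])
    train = np.sort(np.concatenate(train_idx))
    ev = np.sort(np.concatenate(eval_idx))
    return train, ev


def _get_cohort(cfg: RunConfig, seeds: dict[str, int]) -> CohortPair:
    if cfg.data_dir is not None:
        size = cfg.synthetic.image_size if cfg.synthetic is not None else None
        return load_image_dataset(cfg.data_dir, image_size=size, require_manifest=True)
    syn = dataclasses.replace(cfg.synthetic, seed=seeds["cohort"])
    return make_cohort(syn)


def _write_partition(path: Path, part: cda_mod.PartitionedTarget,
                     target_indices: np.ndarray) -> None:
    pd.DataFrame({"target_index": target_indices,
                  "pseudo_label": [CLASS_NAMES[int(l)] for l in part.pseudo_labels]}
                 ).to_csv(path, index=False)


def run_dttl(cfg: RunConfig, out_dir: str | Path | None = None,
             ablate: str | None = None) -> RunReport:
    """Run the full training loop and evaluate on held-out target data."""
    if ablate not in (None, "cda", "cmt"):
        raise ValueError(f"unknown ablation flag: {ablate!r}")
    seeds = _stage_seeds(cfg.seed)
    cohort = _get_cohort(cfg, seeds)
    train_idx, eval_idx = stratified_target_split(
        cohort.target_hidden_labels, cfg.eval_split, seeds["split"])
    t_train = cohort.target_images[train_idx]
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    artifacts: dict[str, str] = {}
    logs: list[pd.DataFrame] = []

    state = None
    n_synth = n_sel = 0
    for it in range(cfg.outer_iterations):
        cda_cfg = dataclasses.replace(cfg.cda, seed=seeds["cda"] + it)
        cmt_cfg = dataclasses.replace(cfg.cmt, seed=seeds["cmt"] + it)
        btl_cfg = dataclasses.replace(cfg.btl, seed=seeds["btl"] + it)
        try:
            state = cda_mod.train_cda(cohort.source, t_train, cda_cfg,
                                      adversarial=(ablate != "cda"))
        except FloatingPointError as exc:
            raise RuntimeError(f"stage cda failed: {exc}") from exc
        _tag_log(logs, state.training_log, "cda", it)
        part = cda_mod.pseudo_label(state, t_train)
        if out is not None:
            p = out / f"partition_iter{it}.csv"
            _write_partition(p, part, train_idx)
            artifacts[f"partition_iter{it}"] = str(p)

        pool = cmt_mod.GeneratedPool(np.zeros((0,) + t_train.shape[1:], np.float32),
                                     np.zeros(0, np.int64))
        selected = np.zeros(0, np.int64)
        if ablate != "cmt":
            if len(part.min) == 0 or len(part.maj) == 0:
                warnings.warn("degenerate pseudo-partition; skipping translation")
            else:
                try:
                    cmt_state = cmt_mod.train_cmt(cohort.source, part, cmt_cfg)
                except FloatingPointError as exc:
                    raise RuntimeError(f"stage cmt failed: {exc}") from exc
                _tag_log(logs, cmt_state.training_log, "cmt", it)
                src_maj = cohort.source.images[cohort.source.labels == MAJ]
                pool = cmt_mod.synthesize_minority(cmt_state, src_maj)
                scores = btl_mod.score_minority_prob(state, pool)
                selected = btl_mod.select_samples(pool, scores, cfg.selection,
                                                  n_min=len(part.min))
        n_synth, n_sel = len(pool), len(selected)
        t_prime = btl_mod.assemble_balanced_target(part, pool, selected)
        if out is not None:
            p = out / f"t_prime_iter{it}.csv"
            pd.DataFrame({"label": [CLASS_NAMES[int(l)] for l in t_prime.labels],
                          "origin": t_prime.origin}).to_csv(p, index=False)
            artifacts[f"t_prime_iter{it}"] = str(p)
        if len(np.unique(t_prime.labels)) < 2:
            warnings.warn("single-class balanced set; skipping balanced training")
        else:
            try:
                state = btl_mod.train_btl(state, t_prime, btl_cfg)
            except FloatingPointError as exc:
                raise RuntimeError(f"stage btl failed: {exc}") from exc

    report = _finalise(state, cohort, eval_idx, cfg, chash,
                       ablation_flags=(ablate,) if ablate else (),
                       n_synth=n_synth, n_sel=n_sel,
                       out=out, artifacts=artifacts, logs=logs)
    return report


def run_ablation(cfg: RunConfig, disable: str,
                 out_dir: str | Path | None = None) -> RunReport:
    """Component-removal run: ``disable`` is 'cda' or 'cmt'."""
    if disable not in ("cda", "cmt"):
        raise ValueError(f"unknown ablation flag: {disable!r}")
    return run_dttl(cfg, out_dir=out_dir, ablate=disable)


def run_source_only(cfg: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """No-adaptation baseline: train F, C on the labeled source only and
    evaluate directly on the held-out target slice."""
    seeds = _stage_seeds(cfg.seed)
    cohort = _get_cohort(cfg, seeds)
    train_idx, eval_idx = stratified_target_split(
        cohort.target_hidden_labels, cfg.eval_split, seeds["split"])
    cda_cfg = dataclasses.replace(cfg.cda, seed=seeds["cda"])
    state = cda_mod.train_source_only(cohort.source,
                                      cohort.target_images[train_idx], cda_cfg)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    return _finalise(state, cohort, eval_idx, cfg, config_hash(cfg),
                     ablation_flags=("source_only",), n_synth=0, n_sel=0,
                     out=out, artifacts={}, logs=[])


def _tag_log(logs: list[pd.DataFrame], log: pd.DataFrame, stage: str, it: int) -> None:
    if len(log):
        log = log.copy()
        log.insert(0, "stage", stage)
        log.insert(1, "outer_iteration", it)
        logs.append(log)


def _finalise(state, cohort, eval_idx, cfg, chash, ablation_flags,
              n_synth, n_sel, out, artifacts, logs) -> RunReport:
    scores = state.minority_score(cohort.target_images[eval_idx])
    report = evaluate(scores, cohort.target_hidden_labels[eval_idx])
    if out is not None:
        report.to_json(out / "metrics.json")
        report.roc_to_csv(out / "roc.csv")
        artifacts["metrics"] = str(out / "metrics.json")
        artifacts["roc"] = str(out / "roc.csv")
        if logs:
            losses = pd.concat(logs, ignore_index=True)
            losses.to_csv(out / "losses.csv", index=False)
            artifacts["losses"] = str(out / "losses.csv")
        ck = out / "final_model.npz"
        save_classifier_checkpoint(state, ck)
        artifacts["checkpoint"] = str(ck)
        (out / "run_report.json").write_text(json.dumps(
            {"auc": report.auc, "config_hash": chash, "seed": cfg.seed,
             "ablation_flags": list(ablation_flags),
             "n_synthesized": n_synth, "n_selected": n_sel}, indent=2))
        artifacts["run_report"] = str(out / "run_report.json")
    return RunReport(eval=report, config_hash=chash, seed=cfg.seed,
                     ablation_flags=tuple(ablation_flags),
                     n_synthesized=n_synth, n_selected=n_sel,
                     stage_artifacts=artifacts)


def save_classifier_checkpoint(state: cda_mod.CDAState, path: str | Path) -> None:
    arrays = {}
    for tag, net in (("f", state.F), ("c", state.C), ("d", state.D)):
        for i, p in enumerate(net.params()):
            arrays[f"{tag}_{i}"] = p.value
    np.savez(path, __hash__=np.array(config_hash(state.cfg), dtype="U32"), **arrays)


def load_classifier_checkpoint(path: str | Path, cfg) -> cda_mod.CDAState:
    state = cda_mod.init_state(cfg)
    with np.load(path) as zf:
        for tag, net in (("f", state.F), ("c", state.C), ("d", state.D)):
            for i, p in enumerate(net.params()):
                p.value = zf[f"{tag}_{i}"].astype(np.float32)
    return state
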