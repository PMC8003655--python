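"""End-to-end experiment orchestration.

Implements the three-model comparison: a *source* model trained on one
facility's (domain A) data, a *target* model trained on the target
facilities' pre-training pool, and per-facility *fine-tuned* models
adapted from the source model with at most ``max_cases`` target cases.
All three are evaluated on the same held-out target test cases and
compared with Welch's ANOVA / Games-Howell; Pearson correlation of Dice
against tumor volume is reported per model type.

For synthetic experiments each split role is generated directly with the
requested number of cases (independent draws); :func:`make_splits`
provides the ratio-based partition (source 60/20/20; target half/half
with the pre-training half split 75/25) for ingesting an unsplit pool of
real cases. All randomness flows from one experiment seed through named
substreams, so a run is reproducible bit-for-bit.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evalstats as es
from .blocknet import NetConfig, SegNet3d, build_network
from .phantoms import FacilitySpec, PhantomCase, TumorSampler, generate_facility_dataset
from .tuner import (
    BASE_TRAIN_SPEC,
    FINE_TUNE_SPEC,
    FreezeStrategy,
    TrainSpec,
    fine_tune,
    sample_finetune_cases,
    train_base,
)
from .volio import bounding_box, crop_resize, merge_voi, support_mask, zscore_normalize

__all__ = [
    "SplitPlan",
    "make_splits",
    "ExperimentConfig",
    "preprocess_case",
    "run_experiment",
    "degradation_recovery",
    "smoke_config",
]

ROLES = (
    "source_train",
    "source_val",
    "source_test",
    "target_pretrain_train",
    "target_pretrain_val",
    "target_test",
)


# ------------------------------------------------------------------- splits


def _largest_remainder(n: int, fracs) -> list[int]:
    """Integer apportionment of n by the given fractions (largest remainder,
    ties broken by earlier position)."""
    quotas = [n * f for f in fracs]
    base = [int(np.floor(q)) for q in quotas]
    short = n - sum(base)
    order = sorted(range(len(fracs)), key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


@dataclass
class SplitPlan:
    """Assignment of every case to exactly one split role."""

    assignment: dict[str, str]
    counts: pd.DataFrame

    def ids(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return sorted(cid for cid, r in self.assignment.items() if r == role)


def make_splits(source_cases, target_cases_by_facility, seed: int,
                source_fracs=(0.6, 0.2, 0.2), pretrain_fracs=(0.75, 0.25)) -> SplitPlan:
    """Partition case ids into the six split roles.

    Source cases: 60/20/20 train/validation/test. Target cases, per
    facility: half pre-training / half test (|difference| <= 1), then
    the pre-training half is split 75/25 train/validation. Deterministic
    given ``seed``; case ids are sorted before shuffling so the plan does
    not depend on input order.
    """
    assignment: dict[str, str] = {}
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 311]))

    src = sorted(str(c) for c in source_cases)
    if len(src) < 2:
        raise ValueError("need at least 2 source cases")
    shuffled = [src[i] for i in rng.permutation(len(src))]
    counts = _largest_remainder(len(src), source_fracs)
    pos = 0
    for role, k in zip(("source_train", "source_val", "source_test"), counts):
        for cid in shuffled[pos:pos + k]:
            assignment[cid] = role
        pos += k
    rows.append({"facility": "<source>", "train": counts[0], "val": counts[1], "test": counts[2]})

    for fid in sorted(target_cases_by_facility):
        ids = sorted(str(c) for c in target_cases_by_facility[fid])
        if len(ids) < 2:
            raise ValueError(f"facility {fid} has fewer than 2 cases")
        shuffled = [ids[i] for i in rng.permutation(len(ids))]
        n_pre, n_test = _largest_remainder(len(ids), (0.5, 0.5))
        pre, test = shuffled[:n_pre], shuffled[n_pre:]
        n_tr, n_va = _largest_remainder(n_pre, pretrain_fracs)
        for cid in pre[:n_tr]:
            assignment[cid] = "target_pretrain_train"
        for cid in pre[n_tr:]:
            assignment[cid] = "target_pretrain_val"
        for cid in test:
            assignment[cid] = "target_test"
        rows.append({"facility": fid, "train": n_tr, "val": n_va, "test": n_test})

    return SplitPlan(assignment=assignment, counts=pd.DataFrame(rows))


# -------------------------------------------------------------- preprocessing


def preprocess_case(case: PhantomCase, target_shape) -> tuple[np.ndarray, np.ndarray]:
    """Phantom case -> (x, y) model arrays.

    Merges sub-region labels to the whole-tumor VOI, crops image and mask
    to the image's in-brain bounding box, resamples to ``target_shape``
    (trilinear / nearest-neighbor) and Z-score normalizes the image.
    """
    voi = merge_voi(case.labels, spacing=case.volume.spacing, identifier=case.case_id)
    box = bounding_box(support_mask(case.volume))
    img = crop_resize(case.volume, target_shape, mode="image", box=box)
    mask = crop_resize(voi, target_shape, mode="mask", box=box)
    img = zscore_normalize(img)
    return img.data.astype(np.float32), mask.data.astype(np.float32)


# ------------------------------------------------------------------- config


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed for one reproducible three-model experiment."""

    source: FacilitySpec
    targets: tuple[FacilitySpec, ...]
    shape: tuple[int, int, int] = (32, 32, 32)
    tumor_sampler: TumorSampler = field(
        default_factory=lambda: TumorSampler(radius_range=(3.0, 5.5))
    )
    net: NetConfig = field(
        default_factory=lambda: NetConfig(
            depth=3, base_channels=8, convs_per_block=1,
            dropout_rate=0.1, target_shape=(32, 32, 32),
        )
    )
    base_spec: TrainSpec = replace(BASE_TRAIN_SPEC, epochs=8)
    ft_spec: TrainSpec = FINE_TUNE_SPEC
    strategy: FreezeStrategy = field(default_factory=lambda: FreezeStrategy("down2_up2"))
    extra_strategies: tuple[str, ...] = ()
    max_cases: int = 20
    n_finetune: int = 10
    n_source_train: int = 40
    n_source_val: int = 8
    n_target_pretrain_train: int = 32
    n_target_pretrain_val: int = 8
    n_target_test: int = 20
    threshold: float = 0.5
    seed: int = 0
    stats_on: str = "cases"  # or "facility_means"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        facs = raw.pop("facilities")
        source = FacilitySpec(facility_id="source", **facs.pop("source"))
        targets = tuple(
            FacilitySpec(facility_id=fid, **params) for fid, params in sorted(facs.items())
        )
        kwargs: dict = {"source": source, "targets": targets}
        if "shape" in raw:
            kwargs["shape"] = tuple(raw.pop("shape"))
        if "tumor_sampler" in raw:
            ts = raw.pop("tumor_sampler")
            if "radius_range" in ts:
                ts["radius_range"] = tuple(ts["radius_range"])
            kwargs["tumor_sampler"] = TumorSampler(**ts)
        if "net" in raw:
            net = raw.pop("net")
            if "target_shape" in net:
                net["target_shape"] = tuple(net["target_shape"])
            kwargs["net"] = NetConfig(**net)
        if "base_spec" in raw:
            kwargs["base_spec"] = TrainSpec(**raw.pop("base_spec"))
        if "ft_spec" in raw:
            kwargs["ft_spec"] = TrainSpec(**raw.pop("ft_spec"))
        if "strategy" in raw:
            s = raw.pop("strategy")
            kwargs["strategy"] = FreezeStrategy(s) if isinstance(s, str) else FreezeStrategy(**s)
        for key in (
            "extra_strategies",
            "max_cases",
            "n_finetune",
            "n_source_train",
            "n_source_val",
            "n_target_pretrain_train",
            "n_target_pretrain_val",
            "n_target_test",
            "threshold",
            "seed",
            "stats_on",
        ):
            if key in raw:
                val = raw.pop(key)
                kwargs[key] = tuple(val) if key == "extra_strategies" else val
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)


# ---------------------------------------------------------------- experiment


def _gen_role(spec, n, cfg, role_tag, seed):
    """Generate and preprocess one split role for one facility."""
    cases = generate_facility_dataset(
        spec,
        n,
        cfg.shape,
        tumor_sampler=cfg.tumor_sampler,
        seed=seed,
        id_prefix=f"{spec.facility_id}_{role_tag}",
    )
    prepped = [preprocess_case(c, cfg.net.target_shape) for c in cases]
    return cases, prepped


def _seed_for(base_seed: int, *tags: str) -> int:
    """Deterministic named substream seed (< 2**31)."""
    h = np.random.SeedSequence([int(base_seed)] + [zlib.crc32(t.encode()) for t in tags])
    return int(h.generate_state(1)[0] >> 1)


def run_experiment(config: ExperimentConfig, out_dir=None):
    """Run the full three-model experiment for one seed.

    Returns a report dict with per-group aggregate tables, Welch ANOVA +
    Games-Howell across model types, per-model-type Pearson r of Dice vs
    tumor volume, and the raw evaluation records. If ``out_dir`` is
    given, writes records CSV, report JSON and checkpoints there.
    """
    cfg = config
    seed = int(cfg.seed)
    records: list[es.EvalRecord] = []

    # --- data ------------------------------------------------------------
    _, src_train = _gen_role(cfg.source, cfg.n_source_train, cfg, "train", _seed_for(seed, "src_train"))
    _, src_val = _gen_role(cfg.source, cfg.n_source_val, cfg, "val", _seed_for(seed, "src_val"))
    per_fac: dict[str, dict] = {}
    for spec in cfg.targets:
        fid = spec.facility_id
        pt_cases, pt = _gen_role(spec, cfg.n_target_pretrain_train, cfg, "pre", _seed_for(seed, "pt", fid))
        pv_cases, pv = _gen_role(spec, cfg.n_target_pretrain_val, cfg, "preval", _seed_for(seed, "pv", fid))
        te_cases, te = _gen_role(spec, cfg.n_target_test, cfg, "test", _seed_for(seed, "te", fid))
        per_fac[fid] = {
            "pretrain": pt, "pretrain_val": pv,
            "test": te, "test_cases": te_cases,
        }

    # --- models ----------------------------------------------------------
    source_model, registry = build_network(cfg.net, seed=_seed_for(seed, "init_src"))
    train_base(source_model, src_train, src_val, replace(cfg.base_spec, seed=_seed_for(seed, "tr_src")))

    target_model, _ = build_network(cfg.net, seed=_seed_for(seed, "init_tgt"))
    pooled_train = [xy for f in per_fac.values() for xy in f["pretrain"]]
    pooled_val = [xy for f in per_fac.values() for xy in f["pretrain_val"]]
    train_base(target_model, pooled_train, pooled_val, replace(cfg.base_spec, seed=_seed_for(seed, "tr_tgt")))

    strategies = [(cfg.strategy, "finetuned")]
    for name in cfg.extra_strategies:
        strategies.append((FreezeStrategy(name, up_convention=cfg.strategy.up_convention),
                           f"finetuned[{name}]"))
    ft_models: dict[tuple[str, str], SegNet3d] = {}
    for fid, data in per_fac.items():
        pool = data["pretrain"]
        if not pool:
            continue
        chosen = sample_finetune_cases(pool, min(cfg.n_finetune, cfg.max_cases),
                                       _seed_for(seed, "ftsample", fid))
        for strat, tag in strategies:
            ft_models[(fid, tag)] = fine_tune(
                source_model, registry, chosen, strat,
                replace(cfg.ft_spec, seed=_seed_for(seed, "ft", fid, tag)),
                max_cases=cfg.max_cases,
            )

    # --- evaluation (paired: same test cases for every model type) -------
    def evaluate(model, fid, tag):
        data = per_fac[fid]
        for (x, y), case in zip(data["test"], data["test_cases"]):
            prob = model.forward(x)
            pred = prob >= cfg.threshold
            truth = y > 0
            denom = pred.sum() + truth.sum()
            if denom == 0:
                continue  # tumor-free case with empty prediction: Dice undefined
            d = 2.0 * float(np.logical_and(pred, truth).sum()) / float(denom)
            records.append(es.EvalRecord(
                case_id=case.case_id, facility_id=fid, model_type=tag,
                dice=d, tumor_volume_ml=case.tumor_volume_ml,
                metadata_label=case.metadata_label,
            ))

    for fid in per_fac:
        evaluate(source_model, fid, "source")
        evaluate(target_model, fid, "target")
        for strat, tag in strategies:
            if (fid, tag) in ft_models:
                evaluate(ft_models[(fid, tag)], fid, tag)

    report = build_report(records, stats_on=cfg.stats_on)
    report["config_seed"] = seed
    report["n_finetuned_models"] = len({f for (f, t) in ft_models if t == "finetuned"})

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        es.write_records(records, out / "eval_records.csv")
        source_model.save(out / "source_model.npz")
        target_model.save(out / "target_model.npz")
        for (fid, tag), m in ft_models.items():
            if tag == "finetuned":
                m.save(out / f"finetuned_{fid}.npz")
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report, records


def build_report(records, stats_on: str = "cases") -> dict:
    """Aggregate records and run the three-group statistical comparison."""
    frame = es.records_to_frame(records)
    core = frame[frame["model_type"].isin(es.MODEL_TYPES)]
    report: dict = {
        "by_model_type": es.aggregate(frame, "model_type").to_dict("records"),
        "by_facility": es.aggregate(frame, "facility_id").to_dict("records"),
        "by_metadata_label": es.aggregate(frame, "metadata_label").to_dict("records"),
    }
    groups, labels = [], []
    for mt in es.MODEL_TYPES:
        sub = core[core["model_type"] == mt]
        if stats_on == "facility_means":
            vals = sub.groupby("facility_id")["dice"].mean().to_numpy()
        else:
            vals = sub["dice"].to_numpy()
        if len(vals):
            groups.append(vals)
            labels.append(mt)
    try:
        f, df1, df2, p = es.welch_anova(groups)
        report["welch_anova"] = {"F": f, "df1": df1, "df2": df2, "p": p}
        report["games_howell"] = es.games_howell(groups, labels).to_dict("records")
    except ValueError as exc:
        report["welch_anova"] = {"error": str(exc)}
        report["games_howell"] = []
    pearson = {}
    for mt in sorted(frame["model_type"].unique()):
        sub = frame[frame["model_type"] == mt]
        try:
            pearson[mt] = es.pearson_r(sub["tumor_volume_ml"], sub["dice"])
        except ValueError as exc:
            pearson[mt] = None
    report["pearson_dice_vs_volume"] = pearson
    return report


# --------------------------------------------------- degradation / recovery


def degradation_recovery(config: ExperimentConfig, seeds=(0, 1, 2, 3, 4)):
    """The domain-shift degradation and fine-tuning recovery experiment.

    Runs the three-model experiment once per seed (with ``fine_all``
    fine-tuning added for comparison) and summarizes, per seed, the mean
    target-test Dice of the source model, the target-trained model, and
    the fine-tuned models. Returns ``(summary, per_seed, records)``.
    """
    cfg = replace(config, extra_strategies=tuple({*config.extra_strategies, "fine_all"}))
    per_seed = []
    all_records = []
    for s in seeds:
        report, records = run_experiment(replace(cfg, seed=int(s)))
        frame = es.records_to_frame(records)
        means = frame.groupby("model_type")["dice"].mean()
        per_seed.append({
            "seed": int(s),
            "source": float(means["source"]),
            "target": float(means["target"]),
            "finetuned": float(means["finetuned"]),
            "fine_all": float(means["finetuned[fine_all]"]),
        })
        for r in records:
            all_records.append(replace(r, case_id=f"s{s}_{r.case_id}"))
    n = len(per_seed)
    summary = {
        "n_seeds": n,
        "mean_dice_source": float(np.mean([r["source"] for r in per_seed])),
        "mean_dice_target": float(np.mean([r["target"] for r in per_seed])),
        "mean_dice_finetuned": float(np.mean([r["finetuned"] for r in per_seed])),
        "mean_dice_fine_all": float(np.mean([r["fine_all"] for r in per_seed])),
        "seeds_degraded": sum(r["source"] < r["target"] for r in per_seed),
        "seeds_recovered": sum(r["finetuned"] > r["source"] for r in per_seed),
        "finetuned_vs_fine_all_gap": float(
            abs(np.mean([r["finetuned"] for r in per_seed]) - np.mean([r["fine_all"] for r in per_seed]))
        ),
    }
    return summary, per_seed, all_records


# ------------------------------------------------------------ stock configs


def recovery_config(seed: int = 0) -> ExperimentConfig:
    """The stock two-facility degradation/recovery configuration.

    Facility A is a near-pristine acquisition; facility B is shifted by
    gamma 1.8, per-channel bias fields of amplitude 0.2, a slice-thickness
    factor of 2 and additive noise sigma 0.08. Sizes: 40 A-train / 8 A-val,
    32/8 B pre-training pool, 20 B-test; fine-tuning uses 10 B cases.
    """
    return ExperimentConfig(
        source=FacilitySpec(facility_id="A", noise_sigma=0.005),
        targets=(
            FacilitySpec(
                facility_id="B", gamma=1.8, noise_sigma=0.08,
                bias_field_amplitude=0.2, slice_thickness_factor=2, rng_seed_offset=1,
            ),
        ),
        seed=seed,
    )


def smoke_config(seed: int = 0) -> ExperimentConfig:
    """Tiny built-in two-facility configuration (seconds-fast)."""
    return ExperimentConfig(
        source=FacilitySpec(facility_id="A", noise_sigma=0.02, bias_field_amplitude=0.05),
        targets=(
            FacilitySpec(
                facility_id="B", gamma=1.8, noise_sigma=0.08,
                bias_field_amplitude=0.2, slice_thickness_factor=2, rng_seed_offset=1,
            ),
        ),
        shape=(16, 16, 16),
        tumor_sampler=TumorSampler(radius_range=(2.5, 4.0), rim_width=0.8, edema_width=1.0,
                                   center_jitter=1.5),
        net=NetConfig(depth=2, base_channels=4, convs_per_block=1, dropout_rate=0.1,
                      target_shape=(16, 16, 16)),
        base_spec=replace(BASE_TRAIN_SPEC, epochs=2),
        ft_spec=replace(FINE_TUNE_SPEC, epochs=2),
        n_source_train=6,
        n_source_val=2,
        n_target_pretrain_train=4,
        n_target_pretrain_val=2,
        n_target_test=4,
        n_finetune=3,
        seed=seed,
    )
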