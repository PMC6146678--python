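"""End-to-end orchestration: train a method, super-resolve images, evaluate.

A :class:`MethodConfig` names one of the nine method back-ends (bicubic
baseline plus eight learned families) with its hyper-parameters; defaults are
the published operating points (NE K=24; B=2048, lambda=0.1; ANR K=40;
A+ K=2048; JOR 32/20/32; SRF T=6, depth 15, kappa=1), except the K-SVD
sparsity L, which defaults to 3 per-code atoms: with 9-dimensional LR
patches any L >= 9 makes OMP an exact interpolator, so the sparse coding
degenerates (see docs/methods.md). The benchmark helper
runs every method on the default synthetic grouped dataset at desk-scale
reductions (B=512, A+ pool 20k, SRF T=3 / depth 10) and emits a metrics report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np

from . import anchored, jor, ne, sparse, srf
from .imaging import (
    Image,
    ImagePair,
    assemble_image,
    bicubic_resize,
    concatenate_patch_sets,
    extract_patches,
    extract_training_patches,
    patch_grid,
    psnr,
    ssim,
)

__all__ = [
    "MethodConfig",
    "MetricsReport",
    "METHODS",
    "default_params",
    "train_model",
    "save_model",
    "load_model",
    "super_resolve_image",
    "evaluate",
    "run_benchmark",
]

log = logging.getLogger("ffasr")

METHODS = (
    "bicubic",
    "ne_ls",
    "ne_nnls",
    "sb_yang",
    "sb_zeyde",
    "anr",
    "aplus",
    "jor",
    "srf",
)

_DEFAULTS: dict[str, dict] = {
    "bicubic": {},
    "ne_ls": {"K": 24, "pool_cap": None},
    "ne_nnls": {"K": 24, "pool_cap": None},
    "sb_yang": {"B": 2048, "lam": 0.1, "n_iters": 5, "train_cap": 5000},
    "sb_zeyde": {"B": 2048, "L": 3, "n_iters": 20, "train_cap": 10000},
    "anr": {"B": 2048, "L": 3, "dict_iters": 20, "K": 40, "lam": 0.1, "train_cap": 10000},
    "aplus": {
        "B": 2048,
        "L": 3,
        "dict_iters": 20,
        "K": 2048,
        "lam": 0.1,
        "train_cap": 10000,
        "pool_cap": 100_000,
    },
    "jor": {"O": 32, "n_iters": 20, "K_select": 32, "lam": 0.1, "train_cap": None},
    "srf": {
        "T": 6,
        "max_depth": 15,
        "lam": 0.1,
        "kappa": 1.0,
        "n_candidates": 32,
        "train_cap": None,
    },
}


def default_params(method: str) -> dict:
    """The published hyper-parameter defaults for ``method``."""
    if method not in _DEFAULTS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return dict(_DEFAULTS[method])


@dataclass(frozen=True)
class MethodConfig:
    """One training/reconstruction configuration."""

    method: str
    factor: int = 2
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.factor not in (2, 4):
            raise ValueError("factor must be 2 or 4")
        merged = default_params(self.method)
        unknown = set(self.params) - set(merged)
        if unknown:
            raise ValueError(f"unknown parameters for {self.method}: {sorted(unknown)}")
        merged.update(self.params)
        object.__setattr__(self, "params", merged)


class BicubicModel:
    """Stub model: the interpolation baseline needs no training."""

    def __init__(self, factor: int):
        self.factor = factor


def _subsample(patches, cap, seed):
    if cap is None or patches.n_pairs <= cap:
        return patches
    pick = np.sort(np.random.default_rng(seed).choice(patches.n_pairs, cap, replace=False))
    import copy

    sub = copy.copy(patches)
    sub.X_l = patches.X_l[:, pick]
    sub.X_h = patches.X_h[:, pick]
    sub.positions = patches.positions[pick]
    sub.lr_means = patches.lr_means[pick]
    return sub


def _zeyde_dictionary(patches, p, seed):
    return sparse.train_zeyde_dictionary(
        _subsample(patches, p["train_cap"], seed),
        b=p["B"],
        l_atoms=p["L"],
        n_iters=p.get("dict_iters", p.get("n_iters", 20)),
        seed=seed,
    )


def train_model(config: MethodConfig, train_pairs: list[ImagePair], base_dictionary=None):
    """Extract patches from all pairs and dispatch to the method's trainer.

    ``base_dictionary`` lets ANR/A+ reuse an already-trained Zeyde dictionary
    (their published starting point) instead of retraining one.
    """
    method, p, seed = config.method, config.params, config.seed
    if method == "bicubic":
        return BicubicModel(config.factor)
    if not train_pairs:
        raise ValueError("empty training set")
    if any(pair.factor != config.factor for pair in train_pairs):
        raise ValueError("training pair factor does not match the config")
    t0 = time.perf_counter()
    patches = concatenate_patch_sets([extract_training_patches(pr) for pr in train_pairs])
    log.info("extracted %d patch pairs in %.2fs", patches.n_pairs, time.perf_counter() - t0)
    if method in ("ne_ls", "ne_nnls"):
        pool = _subsample(patches, p["pool_cap"], seed)
        model = ne.NEModel(
            pool_lr=pool.X_l.copy(),
            pool_hr=pool.X_h.copy(),
            K=p["K"],
            variant=method.removeprefix("ne_"),
            factor=config.factor,
        )
    elif method == "sb_yang":
        model = sparse.train_joint_dictionary(
            _subsample(patches, p["train_cap"], seed),
            b=p["B"],
            lam=p["lam"],
            n_iters=p["n_iters"],
            seed=seed,
        )
    elif method == "sb_zeyde":
        model = _zeyde_dictionary(patches, p, seed)
    elif method in ("anr", "aplus"):
        dic = base_dictionary or _zeyde_dictionary(patches, p, seed)
        model = anchored.build_anchor_projections(
            dic,
            patches=patches if method == "aplus" else None,
            k=p["K"],
            lam=p["lam"],
            variant=method,
            pool_cap=p.get("pool_cap", 100_000),
            seed=seed,
        )
    elif method == "jor":
        model = jor.jor_fit(
            _subsample(patches, p["train_cap"], seed),
            o_count=p["O"],
            n_iters=p["n_iters"],
            lam=p["lam"],
            k_select=p["K_select"],
            seed=seed,
        )
    elif method == "srf":
        model = srf.train_srf(
            _subsample(patches, p["train_cap"], seed),
            n_trees=p["T"],
            max_depth=p["max_depth"],
            lam=p["lam"],
            kappa=p["kappa"],
            n_candidates=p["n_candidates"],
            seed=seed,
        )
    else:  # pragma: no cover - guarded by MethodConfig
        raise ValueError(method)
    log.info("trained %s in %.2fs", method, time.perf_counter() - t0)
    return model


def save_model(model, config: MethodConfig, path) -> None:
    """Self-describing serialized model (joblib container with its config)."""
    joblib.dump({"config": asdict(config), "model": model}, path)


def load_model(path):
    """Returns ``(model, MethodConfig)``."""
    blob = joblib.load(path)
    cfg = blob["config"]
    return blob["model"], MethodConfig(
        method=cfg["method"], factor=cfg["factor"], params=cfg["params"], seed=cfg["seed"]
    )


def super_resolve_image(lr: Image, model, factor: int) -> Image:
    """Patch-wise reconstruction of the HR image from an LR input.

    Dense 3x3/stride-2 LR grid (flush border patches), per-patch model
    prediction on the mean-removed vectors, overlap-averaged reassembly with
    the DC means re-added, clipped to [0, 1].
    """
    if getattr(model, "factor", factor) != factor:
        raise ValueError("model factor does not match the requested factor")
    if isinstance(model, BicubicModel):
        return bicubic_resize(lr, factor * lr.height, factor * lr.width)
    pos = patch_grid(lr.height, lr.width, 3, 2)
    x_l = extract_patches(lr.pixels, pos, 3)
    means = x_l.mean(axis=0)
    hr_patches = model.predict(x_l - means)
    return assemble_image(
        hr_patches, pos, means, (factor * lr.height, factor * lr.width), factor
    )


@dataclass
class MetricsReport:
    """Per-method, per-image PSNR/SSIM with arithmetic-mean aggregates."""

    factor: int
    rows: dict  # method -> {"psnr": [...], "ssim": [...], "mean_psnr", "mean_ssim"}
    config_snapshot: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "factor": self.factor,
            "rows": self.rows,
            "config_snapshot": self.config_snapshot,
            "manifest": self.manifest,
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    def to_csv(self) -> str:
        lines = ["method,mean_psnr_db,mean_ssim,n_images"]
        for method, row in self.rows.items():
            lines.append(
                f"{method},{row['mean_psnr']:.4f},{row['mean_ssim']:.6f},{len(row['psnr'])}"
            )
        return "\n".join(lines) + "\n"

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def evaluate(
    test_pairs: list[ImagePair],
    models: dict[str, object],
    config_snapshot: dict | None = None,
) -> MetricsReport:
    """Super-resolve every test LR image and score against its HR ground truth.

    The bicubic baseline row is always included.
    """
    if not test_pairs:
        raise ValueError("empty test set")
    factor = test_pairs[0].factor
    named = dict(models)
    named.setdefault("bicubic", BicubicModel(factor))
    rows = {}
    for name, model in named.items():
        t0 = time.perf_counter()
        psnrs, ssims = [], []
        for pair in test_pairs:
            sr = super_resolve_image(pair.lr, model, factor)
            psnrs.append(psnr(pair.hr, sr))
            ssims.append(ssim(pair.hr, sr))
        rows[name] = {
            "psnr": psnrs,
            "ssim": ssims,
            "mean_psnr": float(np.mean(psnrs)),
            "mean_ssim": float(np.mean(ssims)),
        }
        log.info(
            "evaluated %s: %.2f dB / %.4f SSIM over %d images (%.1fs)",
            name,
            rows[name]["mean_psnr"],
            rows[name]["mean_ssim"],
            len(psnrs),
            time.perf_counter() - t0,
        )
    return MetricsReport(factor=factor, rows=rows, config_snapshot=config_snapshot or {})


#: Desk-scale reductions used by the default synthetic benchmark.
BENCHMARK_OVERRIDES: dict[str, dict] = {
    "sb_yang": {"B": 512},
    "sb_zeyde": {"B": 512},
    "anr": {"B": 512},
    "aplus": {"B": 512, "K": 2048, "pool_cap": 20_000},
    "srf": {"T": 3, "max_depth": 10},
}


def benchmark_configs(factor: int = 2, seed: int = 0) -> dict[str, MethodConfig]:
    return {
        m: MethodConfig(m, factor=factor, params=BENCHMARK_OVERRIDES.get(m, {}), seed=seed)
        for m in METHODS
    }


def run_benchmark(
    dataset,
    methods: list[str] | None = None,
    seed: int = 0,
    configs: dict[str, MethodConfig] | None = None,
) -> MetricsReport:
    """Train every requested method on the dataset's train split and evaluate.

    ANR and A+ reuse the benchmark's Zeyde dictionary (their published
    starting point) when their dictionary parameters coincide.
    """
    configs = configs or benchmark_configs(factor=dataset.factor, seed=seed)
    methods = list(methods or METHODS)
    models = {}
    dict_cache: dict[tuple, object] = {}
    for m in methods:
        cfg = configs[m]
        base = None
        if m in ("anr", "aplus", "sb_zeyde"):
            key = (
                cfg.params["B"],
                cfg.params["L"],
                cfg.params.get("dict_iters", cfg.params.get("n_iters")),
                cfg.params["train_cap"],
                cfg.seed,
            )
            base = dict_cache.get(key)
            if base is None and m in ("anr", "aplus"):
                zcfg = MethodConfig(
                    "sb_zeyde",
                    factor=cfg.factor,
                    params={
                        "B": cfg.params["B"],
                        "L": cfg.params["L"],
                        "n_iters": cfg.params["dict_iters"],
                        "train_cap": cfg.params["train_cap"],
                    },
                    seed=cfg.seed,
                )
                base = train_model(zcfg, dataset.train_pairs)
                dict_cache[key] = base
        models[m] = train_model(cfg, dataset.train_pairs, base_dictionary=base)
        if m == "sb_zeyde":
            dict_cache[key] = models[m]
    report = evaluate(
        dataset.test_pairs,
        models,
        config_snapshot={m: asdict(configs[m]) for m in methods},
    )
    return report
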