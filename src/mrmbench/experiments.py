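"""Simulation-grid orchestration: method x AF x SNR x pattern x trial.

Every cell derives its own deterministic seeds from ``base_seed`` and the
cell coordinates. Mask and noise are redrawn per trial; mask and noise seeds
do not depend on the method, so different methods see identical data within a
cell and comparisons are paired. Completed cells are persisted as small JSON
records and skipped on re-run, making grids resumable.
"""

from __future__ import annotations

import dataclasses
import json
import time
import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .forward_model import add_noise_for_target_snr, image_to_kspace
from .phantom import Phantom, make_phantom_with_rois
from .recon_classical import cs_l1wavelet_recon, zero_fill_recon
from .recon_zsssl import UnrolledConfig, train_zs_ssl, zs_ssl_reconstruct
from .resolution import fit_blur_sigma
from .sampling import make_sampling_mask
from .snrl_analysis import SNRLCurve, aggregate_trials

__all__ = ["ExperimentConfig", "TrialRecord", "run_condition", "run_grid",
           "compare_patterns", "cell_seed", "scaled_center_radius"]

PAPER_SNR_LEVELS = (4, 6, 8, 10, 15, 20, 30, 50, 100)
PAPER_AFS = (2, 4, 6, 8)


def scaled_center_radius(n: int) -> float:
    """Calibration-disk radius scaled with matrix size (30 at n = 512), so
    the fully sampled k-space fraction matches across problem sizes."""
    return max(4.0, round(30.0 * n / 512.0))


def cell_seed(base_seed: int, *parts) -> int:
    """Deterministic 31-bit seed from the base seed and cell coordinates."""
    tag = "|".join(str(p) for p in parts).encode()
    return (int(base_seed) ^ zlib.crc32(tag)) & 0x7FFFFFFF


@dataclass
class ExperimentConfig:
    """Settings of one simulation grid."""

    n: int = 512
    supersample: int = 8
    methods: tuple = ("zero_fill", "cs_l1w", "zs_ssl")
    afs: tuple = PAPER_AFS
    snr_levels: tuple = PAPER_SNR_LEVELS
    patterns: tuple = (2,)
    n_trials: int = 10
    base_seed: int = 0
    structure_for_beta: tuple = ("circle", 20)
    roi_side: int = 32
    center_radius: float | None = None  # None -> scaled_center_radius(n)
    beta_threshold: float = 1.0
    sigma_bounds: tuple = (0.01, 20.0)
    cs_lam: float = 2e-3
    cs_max_iters: int = 200
    cs_tol: float = 1e-6
    zsssl: UnrolledConfig = field(default_factory=UnrolledConfig)
    output_dir: str | None = None

    def __post_init__(self):
        if not (self.methods and self.afs and self.snr_levels
                and self.patterns and self.n_trials >= 1):
            raise ConfigurationError("grid axes must be non-empty")
        if any(af < 1 for af in self.afs):
            raise ConfigurationError("acceleration factors must be >= 1")

    @property
    def effective_center_radius(self) -> float:
        return (self.center_radius if self.center_radius is not None
                else scaled_center_radius(self.n))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "zsssl" in d and isinstance(d["zsssl"], dict):
            d["zsssl"] = UnrolledConfig(**d["zsssl"])
        for key in ("methods", "afs", "snr_levels", "patterns",
                    "structure_for_beta", "sigma_bounds"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TrialRecord:
    method: str
    af: float
    snr: float
    pattern: int
    trial: int
    seed: int
    beta: float
    sigma: float
    sse: float
    nrmse: float
    runtime_s: float
    extra: dict = field(default_factory=dict)

    def key(self) -> tuple:
        return (self.method, self.af, self.snr, self.pattern, self.trial)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, default=float)

    @classmethod
    def from_json(cls, s: str) -> "TrialRecord":
        return cls(**json.loads(s))


@lru_cache(maxsize=4)
def _phantom_cache(n: int, supersample: int, roi_side: int) -> Phantom:
    return make_phantom_with_rois(n=n, supersample=supersample,
                                  roi_side=roi_side)


@lru_cache(maxsize=4)
def _kspace_cache(n: int, supersample: int, roi_side: int) -> np.ndarray:
    return image_to_kspace(_phantom_cache(n, supersample, roi_side).image)


def _nrmse(magnitude: np.ndarray, ideal: np.ndarray) -> float:
    return float(np.linalg.norm(magnitude - ideal) / np.linalg.norm(ideal))


def run_condition(config: ExperimentConfig, method: str, af: float,
                  snr: float, pattern: int, trial: int) -> TrialRecord:
    """Run one grid cell: draw mask and noise, reconstruct, fit beta."""
    t0 = time.perf_counter()
    ph = _phantom_cache(config.n, config.supersample, config.roi_side)
    k0 = _kspace_cache(config.n, config.supersample, config.roi_side)
    base = config.base_seed

    mask_seed = cell_seed(base, "mask", config.n, af, pattern, trial)
    noise_seed = cell_seed(base, "noise", config.n, snr, trial)
    mask = make_sampling_mask(config.n, af, pattern,
                              center_radius=config.effective_center_radius,
                              seed=mask_seed)
    ks = add_noise_for_target_snr(k0, snr, ph, seed=noise_seed)

    extra = {}
    if method == "zero_fill":
        rec = zero_fill_recon(ks, mask)
    elif method == "cs_l1w":
        rec = cs_l1wavelet_recon(ks, mask, lam=config.cs_lam,
                                 max_iters=config.cs_max_iters,
                                 tol=config.cs_tol)
        extra["iterations"] = rec.params["iterations"]
    elif method == "zs_ssl":
        zc = dataclasses.replace(
            config.zsssl, seed=cell_seed(base, "net", config.n, af, snr,
                                         pattern, trial))
        model, hist = train_zs_ssl(ks, mask, zc)
        rec = zs_ssl_reconstruct(ks, mask, model)
        extra.update({"stop_epoch": hist.stop_epoch,
                      "stop_reason": hist.stop_reason,
                      "best_epoch": hist.best_epoch,
                      "final_val_loss": hist.val_loss[-1]})
    else:
        raise ConfigurationError(f"unknown method {method!r}")

    spec = ph.find_structure(*config.structure_for_beta)
    window = ph.structure_window(spec)
    est = fit_blur_sigma(rec.magnitude, ph.image, window,
                         sigma_bounds=config.sigma_bounds,
                         signal_roi=ph.signal_roi)
    return TrialRecord(
        method=method, af=float(af), snr=float(snr), pattern=int(pattern),
        trial=int(trial),
        seed=cell_seed(base, "cell", method, config.n, af, snr, pattern, trial),
        beta=est.beta, sigma=est.sigma, sse=est.sse,
        nrmse=_nrmse(rec.magnitude, ph.image),
        runtime_s=time.perf_counter() - t0, extra=extra)


def _cell_id(method, af, snr, pattern, trial) -> str:
    return f"{method}_af{af:g}_snr{snr:g}_p{pattern}_t{trial}"


def run_grid(config: ExperimentConfig, progress=None):
    """Execute the whole grid; returns (records, curves, summary table).

    ``curves`` maps (method, af, pattern) -> :class:`SNRLCurve`; the summary
    table is a method x AF pivot of SNR_L per pattern. With ``output_dir``
    set, per-cell JSON records are written and completed cells are skipped on
    re-run; failures are collected and re-raised as a partial-failure report.
    """
    records: list[TrialRecord] = []
    failures: list[tuple[str, str]] = []
    rec_dir = None
    if config.output_dir is not None:
        rec_dir = Path(config.output_dir) / "records"
        rec_dir.mkdir(parents=True, exist_ok=True)

    for method in config.methods:
        for af in config.afs:
            for pattern in config.patterns:
                for snr in config.snr_levels:
                    for trial in range(config.n_trials):
                        cid = _cell_id(method, af, snr, pattern, trial)
                        path = rec_dir / f"{cid}.json" if rec_dir else None
                        if path is not None and path.exists():
                            records.append(TrialRecord.from_json(
                                path.read_text()))
                            continue
                        try:
                            rec = run_condition(config, method, af, snr,
                                                pattern, trial)
                        except Exception as exc:  # collected, reported below
                            failures.append((cid, repr(exc)))
                            continue
                        records.append(rec)
                        if path is not None:
                            path.write_text(rec.to_json())
                        if progress is not None:
                            progress(cid, rec)
    if failures:
        raise RuntimeError("grid cells failed: "
                           + "; ".join(f"{c}: {e}" for c, e in failures))

    curves: dict[tuple, SNRLCurve] = {}
    for method in config.methods:
        for af in config.afs:
            for pattern in config.patterns:
                per_snr = {
                    float(snr): [r.beta for r in records
                                 if r.key()[:4] == (method, float(af),
                                                    float(snr), pattern)]
                    for snr in config.snr_levels}
                curves[(method, float(af), pattern)] = aggregate_trials(
                    per_snr, sorted(float(s) for s in config.snr_levels),
                    threshold=config.beta_threshold)

    rows = []
    for (method, af, pattern), curve in curves.items():
        rows.append({"method": method, "af": af, "pattern": pattern,
                     "snr_l": curve.snr_l})
    summary = pd.DataFrame(rows).pivot_table(
        index="method", columns="af", values="snr_l", aggfunc="first",
        sort=False) if rows else pd.DataFrame()

    if config.output_dir is not None:
        out = Path(config.output_dir)
        beta_rows = []
        for (method, af, pattern), curve in curves.items():
            df = curve.to_frame()
            df.insert(0, "pattern", pattern)
            df.insert(0, "af", af)
            df.insert(0, "method", method)
            beta_rows.append(df)
        pd.concat(beta_rows).to_csv(out / "beta_vs_snr.csv", index=False)
        summary.to_csv(out / "table1.csv")
    return records, curves, summary


def compare_patterns(config: ExperimentConfig, af: float = 4):
    """Per-pattern SNR_L at a fixed AF for a single method; flags the argmin
    pattern (None if no pattern attains a numeric SNR_L)."""
    if len(config.methods) != 1:
        raise ConfigurationError(
            "compare_patterns expects exactly one method in the config")
    method = config.methods[0]
    cfg = dataclasses.replace(config, afs=(af,))
    _, curves, _ = run_grid(cfg)
    per_pattern = {p: curves[(method, float(af), p)] for p in config.patterns}
    numeric = {p: c.snr_l for p, c in per_pattern.items()
               if isinstance(c.snr_l, float)}
    best = min(numeric, key=numeric.get) if numeric else None
    return per_pattern, best
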