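"""Synthetic trial data with the structure the pipeline assumes.

No patient-level data from the source trials is available, so testing the
reconstruction → fitting → partitioned-survival → CEA chain end-to-end
requires emulating it: log-normal OS/PFS event times with the configured
(meanlog, sdlog), per-patient PFS <= OS by construction, uniform accrual
with administrative censoring at study end, digitization of the resulting
KM curves on a coarse grid with optional jitter, and exact numbers-at-risk
tables.

The OS/PFS dependence is comonotone — one shared uniform drives both
marginals, then PFS is truncated at OS — the simplest joint model
satisfying the marginals and the ordering constraint.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ipd_tools import DigitizedCurve, PseudoIPD, km_estimate
from .parameters import ModelConfig, default_config
from .survival import ParametricSurvival

__all__ = [
    "TrialFixture",
    "generate_trial_ipd",
    "digitize_curve",
    "make_fixture_bundle",
]


@dataclass(frozen=True)
class TrialFixture:
    """Ground truth for one synthetic trial arm (times in months)."""

    arm: str
    os: ParametricSurvival
    pfs: ParametricSurvival
    n: int
    accrual_months: float = 12.0
    followup_months: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("need at least 10 patients")
        if self.accrual_months < 0 or self.followup_months <= 0:
            raise ValueError("infeasible accrual/follow-up windows")


def _quantile(dist: ParametricSurvival, u: np.ndarray) -> np.ndarray:
    """Inverse CDF via bisection on the survival function (u = CDF value)."""
    lo = np.zeros_like(u)
    hi = np.full_like(u, 1.0)
    # expand upper bracket
    for _ in range(60):
        need = dist.survival(hi) > 1.0 - u
        if not np.any(need):
            break
        hi = np.where(need, hi * 2.0, hi)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        high_enough = dist.survival(mid) <= 1.0 - u
        hi = np.where(high_enough, mid, hi)
        lo = np.where(high_enough, lo, mid)
    return 0.5 * (lo + hi)


def generate_trial_ipd(fix: TrialFixture) -> tuple[PseudoIPD, PseudoIPD]:
    """Draw one synthetic trial; returns (os_ipd, pfs_ipd).

    A shared uniform drives both endpoints (comonotone dependence), PFS is
    truncated at OS, entry is uniform over the accrual window and both
    endpoints are administratively censored at study end.
    """
    rng = np.random.default_rng(fix.seed)
    u = rng.uniform(size=fix.n)
    os_t = _quantile(fix.os, u)
    pfs_t = np.minimum(_quantile(fix.pfs, u), os_t)
    entry = rng.uniform(0.0, fix.accrual_months, size=fix.n)
    cens = fix.accrual_months + fix.followup_months - entry

    def pack(times):
        ev = times <= cens
        obs = np.where(ev, times, cens)
        obs = np.maximum(obs, 1e-6)
        return PseudoIPD(tuple(obs), tuple(int(x) for x in ev))

    return pack(os_t), pack(pfs_t)


def digitize_curve(
    ipd: PseudoIPD,
    grid_step: float = 0.25,
    jitter_sd: float = 0.0,
    seed: int = 0,
    risk_step: float = 3.0,
) -> DigitizedCurve:
    """Emulate reading a KM plot: grid sampling, jitter, exact risk table."""
    if grid_step <= 0:
        raise ValueError("grid step must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    km = km_estimate(ipd)
    t_max = max(ipd.time)
    grid = np.arange(0.0, t_max + grid_step / 2, grid_step)
    probs = np.asarray(km(grid), dtype=float)
    if jitter_sd > 0:
        probs = probs + np.clip(
            rng.normal(0.0, jitter_sd, size=probs.size), -3 * jitter_sd, 3 * jitter_sd
        )
        probs = np.clip(probs, 0.0, 1.0)
    probs[0] = 1.0
    risk_times = np.arange(0.0, t_max, risk_step)
    t_arr = np.asarray(ipd.time)
    risk_n = [(t_arr >= rt).sum() for rt in risk_times]
    keep = [i for i, n in enumerate(risk_n) if n > 0]
    return DigitizedCurve(
        times=tuple(grid),
        probs=tuple(probs),
        risk_times=tuple(float(risk_times[i]) for i in keep),
        risk_n=tuple(int(risk_n[i]) for i in keep),
        total_events=ipd.n_events,
    )


def _write_ipd(path: Path, ipd: PseudoIPD) -> None:
    with open(path, "w") as fh:
        fh.write("time_months\tevent\n")
        for t, e in zip(ipd.time, ipd.event):
            fh.write(f"{t:.6f}\t{e}\n")


def make_fixture_bundle(
    out_dir, n: int = 300, seed: int = 0, cfg: ModelConfig | None = None
) -> dict:
    """Write a three-arm synthetic fixture set plus a manifest.

    Per arm: OS and PFS pseudo-IPD (tab-delimited), a digitized OS curve
    with its risk table, and sha256 checksums in ``manifest.json`` —
    stable across runs for a fixed seed.
    """
    cfg = cfg or default_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "n": n, "files": {}}
    from .parameters import dump_model_config

    p = out / "model_config.cfg"
    p.write_text(dump_model_config(cfg))
    manifest["files"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    for k, strat in enumerate(cfg.strategies):
        fix = TrialFixture(
            arm=strat.name, os=strat.os, pfs=strat.pfs, n=n, seed=seed + k
        )
        os_ipd, pfs_ipd = generate_trial_ipd(fix)
        safe = strat.name.replace("/", "-")
        for tag, ipd in (("os", os_ipd), ("pfs", pfs_ipd)):
            p = out / f"{safe}_{tag}_ipd.tsv"
            _write_ipd(p, ipd)
            manifest["files"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        dig = digitize_curve(os_ipd, seed=seed + k)
        p = out / f"{safe}_os_digitized.tsv"
        with open(p, "w") as fh:
            fh.write("time_months\tsurvival\n")
            for t, s in zip(dig.times, dig.probs):
                fh.write(f"{t:.4f}\t{s:.6f}\n")
            fh.write("# risk table\n")
            for t, nn in zip(dig.risk_times, dig.risk_n):
                fh.write(f"#risk\t{t:.4f}\t{nn}\n")
        manifest["files"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
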