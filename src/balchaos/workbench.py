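"""Experiment orchestration: configuration files, seed derivation,
serialisation (HDF5 / CSV / JSON) and figure rendering.

A structured YAML config selects a pipeline (simulate | lyapunov | dmft |
dmft-stationary | quasi-static | crit-amp | sweep | fullforce) and its
parameters; :func:`run_experiment` executes it into an artifact directory
together with a manifest (config hash, derived seeds, package version,
wall time).  Every stochastic component's seed is derived deterministically
from the global seed and a stable component label, so a rerun with the
same config reproduces the same numbers.

:func:`make_figures` renders plots strictly from the saved artifacts (no
recomputation at plot time).
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd
import yaml

from balchaos import __version__
from balchaos.critical import sweep as run_sweep
from balchaos.critical import dmft_lambda1_factory, find_critical_amplitude
from balchaos.dmft import GridSpec, dmft_autocorr, solve_mcr, solve_tangent
from balchaos.dmft_stationary import (
    solve_autonomous,
    solve_independent_drive,
    stationary_phi_autocorr,
)
from balchaos.fullforce import evaluate, run_teacher, train_student
from balchaos.lyapunov import le_replica, le_tangent
from balchaos.network import (
    EIConfig,
    InputProtocol,
    NetworkConfig,
    build_coupling,
    build_ei_coupling,
    simulate,
)
from balchaos.quasistatic import qs_crit_ou, qs_crit_sin, qs_lambda1_ou, qs_lambda1_sin

__all__ = ["seed_for", "load_config", "run_experiment", "make_figures"]

KINDS = (
    "simulate", "lyapunov", "dmft", "dmft-stationary", "quasi-static",
    "crit-amp", "sweep", "fullforce",
)


def seed_for(global_seed: int, label: str, index: int = 0) -> int:
    """Deterministic per-component seed below 2**31."""
    h = zlib.crc32(label.encode()) & 0xFFFFFFFF
    ss = np.random.SeedSequence([int(global_seed), h, int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "kind" not in cfg:
        raise ValueError("config must be a mapping with a 'kind' entry")
    if cfg["kind"] not in KINDS:
        raise ValueError(f"unknown pipeline kind {cfg['kind']!r}")
    return cfg


def _network_from(cfg: dict):
    d = dict(cfg.get("network", {}))
    if "N_E" in d:
        return EIConfig(**d)
    return NetworkConfig(**d)


def _protocol_from(cfg: dict, seed: int) -> InputProtocol:
    d = dict(cfg.get("input", {}))
    d.setdefault("kind", "none")
    d.setdefault("seed", seed_for(seed, "input"))
    return InputProtocol(**d)


def _grid_from(cfg: dict) -> GridSpec:
    d = dict(cfg.get("grid", {}))
    return GridSpec(**d) if d else GridSpec()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def save_trajectory(path: Path, traj, extra_attrs: Optional[dict] = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("h", data=traj.h)
        f.create_dataset("nu", data=traj.nu())
        f.attrs["dt"] = traj.dt
        f.attrs["stride"] = traj.stride
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v


def save_dmft(path: Path, sol, tangent=None, autocorr=None) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("grid")
        grp.create_dataset("times", data=sol.times)
        grp.create_dataset("m", data=sol.m)
        grp.create_dataset("nu", data=sol.nu)
        grp.create_dataset("c", data=sol.c)
        if sol.r is not None:
            grp.create_dataset("r", data=sol.r)
        if tangent is not None:
            tg = f.create_group("tangent")
            tg.create_dataset("log_k_diag", data=tangent.log_k_diag)
            f.attrs["lambda1"] = tangent.lambda1
            f.attrs["fit_rsq"] = tangent.fit_rsq
        if autocorr is not None:
            ac = f.create_group("autocorr")
            ac.create_dataset("lags", data=autocorr[0])
            ac.create_dataset("cbar", data=autocorr[1])


def run_experiment(
    config: Union[str, Path, dict],
    out_dir: Union[str, Path],
    seed: Optional[int] = None,
) -> Path:
    """Execute the configured pipeline; artifacts plus manifest in out_dir."""
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    cfg.setdefault("seed", 0)
    gseed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    kind = cfg["kind"]
    seeds_used = {}
    summary = {}

    if kind == "simulate":
        net = _network_from(cfg)
        protocol = _protocol_from(cfg, gseed)
        integ = cfg.get("integration", {})
        cseed = seed_for(gseed, "coupling")
        seeds_used["coupling"] = cseed
        J = (build_ei_coupling(net, cseed) if isinstance(net, EIConfig)
             else build_coupling(net, cseed))
        traj = simulate(
            J, net, protocol,
            T=float(integ.get("T", 100.0)), dt=float(integ.get("dt", 0.01)),
            seed=seed_for(gseed, "init"),
            store_stride=integ.get("store_stride"),
            method=integ.get("method", "heun"),
        )
        save_trajectory(out / "trajectory.h5", traj)
        summary = {"nu_mean": float(traj.nu().mean()),
                   "nu_final": float(traj.nu()[-1])}

    elif kind == "lyapunov":
        net = _network_from(cfg)
        protocol = _protocol_from(cfg, gseed)
        opts = cfg.get("lyapunov", {})
        cseed = seed_for(gseed, "coupling")
        seeds_used["coupling"] = cseed
        J = (build_ei_coupling(net, cseed) if isinstance(net, EIConfig)
             else build_coupling(net, cseed))
        method = opts.get("method", "tangent")
        kwargs = dict(
            T_transient=float(opts.get("T_transient", 50.0)),
            T_measure=float(opts.get("T_measure", 200.0)),
            dt=float(opts.get("dt", 0.02)),
            seed=seed_for(gseed, "lyapunov"),
        )
        if method == "tangent":
            est = le_tangent(J, net, protocol, **kwargs)
        else:
            est = le_replica(J, net, protocol, **kwargs)
        summary = {"lambda1": est.lambda1, "stderr": est.stderr,
                   "method": est.method}

    elif kind == "dmft":
        net = _network_from(cfg)
        protocol = _protocol_from(cfg, gseed)
        grid = _grid_from(cfg)
        sol = solve_mcr(net, protocol, grid)
        tg = solve_tangent(sol)
        max_lag = float(cfg.get("analysis", {}).get("max_lag", 10.0))
        ac = dmft_autocorr(sol, max_lag)
        save_dmft(out / "dmft.h5", sol, tg, ac)
        summary = {"lambda1": tg.lambda1, "fit_rsq": tg.fit_rsq,
                   "nu_mean": float(sol.nu[sol.n_transient:].mean())}

    elif kind == "dmft-stationary":
        net = _network_from(cfg)
        inp = cfg.get("input", {})
        if inp.get("kind", "none") == "independent_sin":
            protocol = _protocol_from(cfg, gseed)
            sol = solve_independent_drive(net, protocol)
        else:
            sol = solve_autonomous(net)
        lags, cbar = stationary_phi_autocorr(sol)
        with h5py.File(out / "stationary.h5", "w") as f:
            grp = f.create_group("stationary")
            grp.create_dataset("lags", data=sol.lags)
            grp.create_dataset("c_resid", data=sol.c_resid)
            grp.create_dataset("cbar_phiphi", data=cbar)
            f.attrs["m"] = sol.m
            f.attrs["nu"] = sol.nu
            f.attrs["A"] = sol.A
            f.attrs["lambda1"] = sol.lambda1
        summary = {"m": sol.m, "nu": sol.nu, "lambda1": sol.lambda1,
                   "A": sol.A, "iterations": sol.iterations}

    elif kind == "quasi-static":
        qs = cfg.get("quasi_static", {})
        g_values = qs.get("g_values", [1.6, 2.0])
        N = float(qs.get("N", 5000))
        I0 = float(qs.get("I0", 1.0))
        rows = []
        for g in g_values:
            row = {"g": g, "I1crit_sin": qs_crit_sin(g, N, I0)}
            if "tau_s" in qs:
                row["Dcrit_ou"] = qs_crit_ou(g, float(qs["tau_s"]), N, I0)
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "quasi_static.csv", index=False)
        summary = {"n_points": len(rows)}

    elif kind == "crit-amp":
        net = _network_from(cfg)
        ca = cfg.get("crit_amp", {})
        fn = dmft_lambda1_factory(net, ca.get("input_type", "common"),
                                  float(ca.get("f", 0.2)))
        bracket = tuple(ca.get("bracket", (0.1, 2.0 * np.sqrt(net.N) * net.i0_eff)))
        res = find_critical_amplitude(fn, bracket,
                                      rel_tol=float(ca.get("rel_tol", 0.01)))
        summary = {"I1crit": res.value, "bracket": list(res.bracket),
                   "n_evals": res.n_evals}

    elif kind == "sweep":
        net = _network_from(cfg)
        sw = cfg.get("sweep", {})
        n_real = int(sw.get("n_realizations", 10))
        seeds = [seed_for(gseed, "sweep-coupling", i) for i in range(n_real)]
        seeds_used["sweep"] = seeds
        df = run_sweep(
            axis=sw["axis"], values=sw["values"], base_config=net,
            input_type=sw.get("input_type", "common"), f=float(sw.get("f", 0.2)),
            method=sw.get("method", "dmft"), seeds=seeds,
        )
        df.to_csv(out / "sweep.csv", index=False)
        summary = {"n_rows": len(df),
                   "n_failed": int(df["I1crit"].isna().sum())}

    elif kind == "fullforce":
        net = _network_from(cfg)
        protocol = _protocol_from(cfg, gseed)
        lr = cfg.get("learning", {})
        tseed = seed_for(gseed, "teacher")
        seeds_used["teacher"] = tseed
        teach = run_teacher(net, protocol,
                            n_periods=int(lr.get("n_train_periods", 10)),
                            dt=float(lr.get("dt", 0.01)), seed=tseed)
        res = train_student(teach, beta=float(lr.get("beta", 1.0)),
                            max_passes=int(lr.get("max_passes", 20)),
                            seed=seed_for(gseed, "student"))
        e_test = evaluate(res, n_periods=int(lr.get("n_test_periods", 50)))
        summary = {"lambda1_teacher": teach.lambda1.lambda1,
                   "lambda1_stderr": teach.lambda1.stderr,
                   "E_test": e_test, "I1": protocol.I1,
                   "input_type": protocol.kind, "passes": res.passes_run}
        with h5py.File(out / "fullforce.h5", "w") as f:
            f.create_dataset("train_error", data=np.asarray(res.train_error))
            f.create_dataset("test_error_trace",
                             data=np.asarray(res.test_error_trace))
            f.create_dataset("w", data=res.w)
            f.attrs["E_test"] = e_test

    else:  # pragma: no cover - guarded by load_config
        raise ValueError(f"unknown kind {kind!r}")

    manifest = {
        "kind": kind,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "global_seed": gseed,
        "derived_seeds": seeds_used,
        "version": __version__,
        "wall_time_s": round(time.time() - t_start, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return out


def make_figures(artifact_dir: Union[str, Path], allow_partial: bool = False):
    """Render figures from saved artifacts only.  Returns the list of files
    written; raises if expected inputs are missing (unless allow_partial)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    art = Path(artifact_dir)
    written = []
    missing = []

    traj_file = art / "trajectory.h5"
    if traj_file.exists():
        with h5py.File(traj_file) as f:
            times = f["times"][:]
            nu = f["nu"][:]
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot(times, nu, lw=0.8)
        ax.set_xlabel(r"$t/\tau$")
        ax.set_ylabel(r"population rate $\nu(t)$")
        fig.tight_layout()
        p = art / "fig_population_rate.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    dmft_file = art / "dmft.h5"
    if dmft_file.exists():
        with h5py.File(dmft_file) as f:
            times = f["grid/times"][:]
            nu = f["grid/nu"][:]
            has_ac = "autocorr" in f
            if has_ac:
                lags = f["autocorr/lags"][:]
                cbar = f["autocorr/cbar"][:]
        fig, axes = plt.subplots(1, 2 if has_ac else 1, figsize=(8, 3))
        axes = np.atleast_1d(axes)
        axes[0].plot(times, nu)
        axes[0].set_xlabel(r"$t/\tau$")
        axes[0].set_ylabel(r"$\nu(t)$ (DMFT)")
        if has_ac:
            axes[1].plot(np.concatenate([-lags[::-1], lags]),
                         np.concatenate([cbar[::-1], cbar]))
            axes[1].set_xlabel(r"lag $\Delta/\tau$")
            axes[1].set_ylabel(r"$\bar{C}_{\phi\phi}(\Delta)$")
        fig.tight_layout()
        p = art / "fig_dmft.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    sweep_file = art / "sweep.csv"
    if sweep_file.exists():
        df = pd.read_csv(sweep_file)
        if df["I1crit"].isna().any() and not allow_partial:
            raise RuntimeError(
                "sweep contains failed points; pass allow_partial=True to render"
            )
        fig, ax = plt.subplots(figsize=(5, 3))
        for itype, sub in df.groupby("input_type"):
            agg = sub.groupby("axis_value")["I1crit"].median()
            ax.loglog(agg.index, agg.values, "o-", label=itype)
        ax.set_xlabel(df["axis"].iloc[0])
        ax.set_ylabel(r"$I_1^{\rm crit}$")
        ax.legend()
        fig.tight_layout()
        p = art / "fig_sweep.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    if not written:
        missing.append("no renderable artifacts found")
    if missing and not allow_partial:
        raise FileNotFoundError("; ".join(str(m) for m in missing))
    return written
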