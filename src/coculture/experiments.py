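"""Parameter sweeps, example cultural transition graphs, and config runs.

Sweeps evaluate the exact solver over grids of population size, fitness
difference, rate of cultural change and amplification, emitting tidy
pandas tables (one independently recomputable solve per cell).  Also
provides the amplification-curve export, builders for richer cultural
transition graphs (a one-way chain of states and a mixed-state
nearest-neighbour chain), and a small config-file front end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classic_moran import solve_classic
from .core_model import (
    PREFERRED,
    CompositionState,
    CoupledModel,
    LanguageModelParams,
    ParameterError,
    amplification_pi,
    build_custom_model,
    build_language_model,
)
from .coupled_solver import solve_model
from .simulator import estimate_fixation

__all__ = [
    "SweepSpec",
    "DEFAULT_GRIDS",
    "sweep_population_fitness",
    "sweep_eta",
    "sweep_amplification",
    "pi_curve",
    "unidirectional_chain",
    "mixed_chain",
    "run_config",
]

#: Default grids bracketing the headline parameter settings.
DEFAULT_GRIDS = {
    "N": [100, 500, 1500, 15000],
    "phi": [0.0, 0.01, 0.1, 0.3],
    "eta": [0.0, 0.01, 0.1, 0.5, 1.0],
    "alpha": [0.25, 1.0, 4.0],
    "beta": [0.0, 0.5, 1.0],
}


@dataclass
class SweepSpec:
    """A named sweep with grids, held parameters and requested outputs."""

    family: str
    grids: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    units: str = "generations"

    _FAMILIES = ("population_fitness", "eta", "amplification", "pi_curve")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ParameterError(
                f"unknown sweep family {self.family!r}; choose from {self._FAMILIES}"
            )
        for key, values in self.grids.items():
            if len(values) == 0:
                raise ParameterError(f"grid {key!r} is empty")


def _solve_cell(params: LanguageModelParams, units: str):
    """One grid cell: coupled and classic quantities at matched parameters."""
    model = build_language_model(params)
    res = solve_model(model, units=units)
    c = model.state_index(params.start_state)
    eps_c = float(res.epsilon[1, c])
    t_c = float(res.t_conditional[1, c])
    classic = solve_classic(params.N, params.phi, units=units)
    eps_0 = float(classic.epsilon[1])
    t_0 = float(classic.t_conditional[1])
    return {
        "epsilon_culture": eps_c,
        "t_culture": t_c,
        "epsilon_classic": eps_0,
        "t_classic": t_0,
        "prob_ratio": eps_c / eps_0 if eps_0 > 0 else np.nan,
        "time_ratio": t_c / t_0 if t_0 > 0 else np.nan,
    }


def sweep_population_fitness(spec: SweepSpec) -> pd.DataFrame:
    """Fixation probability and time over (N, phi), with and without culture."""
    Ns = spec.grids.get("N", DEFAULT_GRIDS["N"])
    phis = spec.grids.get("phi", DEFAULT_GRIDS["phi"])
    fixed = {"eta": 0.1, "alpha": 1.0, "beta": 1.0, **spec.fixed}
    rows = []
    for N in Ns:
        for phi in phis:
            params = LanguageModelParams(N=int(N), phi=float(phi), **fixed)
            rows.append({"N": N, "phi": phi, **_solve_cell(params, spec.units)})
    return pd.DataFrame(rows)


def sweep_eta(spec: SweepSpec) -> pd.DataFrame:
    """Fixation probability and time over (eta, N) at fixed phi, alpha, beta."""
    etas = spec.grids.get("eta", DEFAULT_GRIDS["eta"])
    Ns = spec.grids.get("N", DEFAULT_GRIDS["N"])
    fixed = {"phi": 0.1, "alpha": 1.0, "beta": 1.0, **spec.fixed}
    rows = []
    for N in Ns:
        for eta in etas:
            params = LanguageModelParams(N=int(N), eta=float(eta), **fixed)
            rows.append({"eta": eta, "N": N, **_solve_cell(params, spec.units)})
    return pd.DataFrame(rows)


def sweep_amplification(spec: SweepSpec) -> pd.DataFrame:
    """Fixation probability and time over (alpha, beta) at fixed N, eta, phi."""
    alphas = spec.grids.get("alpha", DEFAULT_GRIDS["alpha"])
    betas = spec.grids.get("beta", DEFAULT_GRIDS["beta"])
    fixed = {"N": 1500, "eta": 0.1, "phi": 0.1, **spec.fixed}
    rows = []
    for alpha in alphas:
        for beta in betas:
            params = LanguageModelParams(alpha=float(alpha), beta=float(beta), **fixed)
            rows.append(
                {"alpha": alpha, "beta": beta, **_solve_cell(params, spec.units)}
            )
    return pd.DataFrame(rows)


def pi_curve(alpha_list, beta_list, x_grid) -> pd.DataFrame:
    """Tabulate the amplification curve pi(x) for each (alpha, beta) pair."""
    x = np.asarray(x_grid, dtype=float)
    rows = []
    for alpha in alpha_list:
        for beta in beta_list:
            pi = amplification_pi(x, alpha, beta)
            for xi, pii in zip(x, np.atleast_1d(pi)):
                rows.append({"alpha": alpha, "beta": beta, "x": xi, "pi": pii})
    return pd.DataFrame(rows)


def unidirectional_chain(k: int, rate, rate_fn=None):
    """Kernel builder for a one-way chain of ``k`` cultural states.

    Each state ``c`` moves to ``c + 1`` with the given per-event probability
    (the last state is absorbing); no backward edges exist, so earlier
    states can never be revisited.  ``rate_fn(i) -> probability`` makes the
    forward rate depend on the biological composition; otherwise ``rate``
    is constant.  Returns a function ``i -> (k, k)`` row-stochastic matrix
    suitable for :func:`~coculture.core_model.build_custom_model`.
    """
    if k < 2:
        raise ParameterError("a chain needs at least two states")

    def kernel(i: int) -> np.ndarray:
        r = float(rate_fn(i)) if rate_fn is not None else float(rate)
        if not 0 <= r <= 1:
            raise ParameterError(f"forward rate must lie in [0, 1], got {r}")
        mat = np.eye(k)
        for c in range(k - 1):
            mat[c, c] = 1.0 - r
            mat[c, c + 1] = r
        return mat

    return kernel


def mixed_chain(rate_up, rate_down, rate_fn=None):
    """Kernel builder for the pure/mixed/pure three-state cultural graph.

    States are ``0%``, ``50%`` and ``100%`` adoption of one variant; only
    nearest-neighbour moves are allowed (a pure culture must pass through
    the mixed state).  ``rate_up`` moves toward ``100%``, ``rate_down``
    toward ``0%``; ``rate_fn(i) -> (up, down)`` adds composition
    dependence.  Returns a function ``i -> (3, 3)`` matrix.
    """

    def kernel(i: int) -> np.ndarray:
        up, down = rate_fn(i) if rate_fn is not None else (rate_up, rate_down)
        up, down = float(up), float(down)
        if min(up, down) < 0 or up + down > 1:
            raise ParameterError(
                f"need nonnegative rates with up + down <= 1, got ({up}, {down})"
            )
        return np.array(
            [
                [1.0 - up, up, 0.0],
                [down, 1.0 - up - down, up],
                [0.0, down, 1.0 - down],
            ]
        )

    return kernel


MIXED_CHAIN_LABELS = ("0%", "50%", "100%")


def _model_from_config(cfg: dict) -> tuple:
    family = cfg.get("family", "language_two_state")
    if family == "language_two_state":
        params = LanguageModelParams(
            N=int(cfg["N"]),
            phi=float(cfg["phi"]),
            eta=float(cfg["eta"]),
            alpha=float(cfg.get("alpha", 1.0)),
            beta=float(cfg.get("beta", 1.0)),
            start_state=str(cfg.get("start_state", PREFERRED)),
        )
        return build_language_model(params), params
    if family == "custom":
        labels = list(cfg["state_labels"])
        kernel_spec = cfg["kernel_spec"]
        kind = kernel_spec["kind"]
        if kind == "constant":
            kernel = np.asarray(kernel_spec["matrix"], dtype=float)
        elif kind == "tabulated":
            kernel = np.asarray(kernel_spec["matrices"], dtype=float)
        elif kind == "unidirectional_chain":
            kernel = unidirectional_chain(len(labels), kernel_spec["rate"])
        elif kind == "mixed_chain":
            kernel = mixed_chain(kernel_spec["rate_up"], kernel_spec["rate_down"])
        else:
            raise ParameterError(f"config field kernel_spec.kind: unknown kind {kind!r}")
        model = build_custom_model(
            N=int(cfg["N"]),
            state_labels=labels,
            advantage=np.asarray(cfg["fitness_table"], dtype=float),
            kernel=kernel,
        )
        return model, None
    raise ParameterError(f"config field family: unknown family {family!r}")


def run_config(path, out=None, verbose: bool = False):
    """Execute a solve / sweep / simulation described by a YAML or JSON file.

    The file carries a model section (see :func:`_model_from_config`) and an
    optional ``action`` (``solve`` — the default, ``simulate``, or
    ``sweep`` with a nested :class:`SweepSpec`).  Results are written to
    ``out`` (CSV for tables, JSON for scalars) with a metadata header and
    also returned.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParameterError(f"config {path} did not parse to a mapping")
    action = cfg.get("action", "solve")
    units = cfg.get("units", "generations")
    meta = {
        "package": "coculture",
        "version": __version__,
        "config": str(path),
        "units": units,
    }

    if action == "sweep":
        spec_cfg = cfg.get("sweep", {})
        spec = SweepSpec(
            family=spec_cfg.get("family", "eta"),
            grids=spec_cfg.get("grids", {}),
            fixed=spec_cfg.get("fixed", {}),
            units=units,
        )
        runner = {
            "population_fitness": sweep_population_fitness,
            "eta": sweep_eta,
            "amplification": sweep_amplification,
        }
        if spec.family == "pi_curve":
            table = pi_curve(
                spec.grids.get("alpha", DEFAULT_GRIDS["alpha"]),
                spec.grids.get("beta", DEFAULT_GRIDS["beta"]),
                spec.grids.get("x", np.linspace(0, 1, 101)),
            )
        else:
            table = runner[spec.family](spec)
        if out is not None:
            _write_table(table, meta, out)
        return table

    model, params = _model_from_config(cfg.get("model", cfg))
    if action == "solve":
        res = solve_model(model, units=units, params_echo=params)
        start_label = params.start_state if params is not None else model.state_labels[0]
        c = model.state_index(start_label)
        payload = {
            **meta,
            "epsilon_start": float(res.epsilon[1, c]),
            "t_start": float(res.t_conditional[1, c]),
            "epsilon_by_state": {
                lab: float(res.epsilon[1, j])
                for j, lab in enumerate(model.state_labels)
            },
            "t_by_state": {
                lab: float(res.t_conditional[1, j])
                for j, lab in enumerate(model.state_labels)
            },
        }
        if out is not None:
            Path(out).write_text(json.dumps(payload, indent=2) + "\n")
        if verbose:
            print(json.dumps(payload, indent=2))
        return payload
    if action == "simulate":
        sim_cfg = cfg.get("simulate", {})
        start_label = (
            params.start_state if params is not None else model.state_labels[0]
        )
        est = estimate_fixation(
            model,
            CompositionState(int(sim_cfg.get("start_i", 1)), start_label),
            n_runs=int(sim_cfg.get("runs", 10000)),
            seed=int(sim_cfg.get("seed", 0)),
            max_steps=int(sim_cfg.get("max_steps", 10**9)),
            units=units,
        )
        payload = {**meta, **est.__dict__}
        if out is not None:
            Path(out).write_text(json.dumps(payload, indent=2) + "\n")
        return payload
    raise ParameterError(f"config field action: unknown action {action!r}")


def _write_table(table: pd.DataFrame, meta: dict, out) -> None:
    out = Path(out)
    with open(out, "w", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, index=False)
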