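"""Trial tables, plain-text configuration, and prior serialization."""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .data import SurvivalDataset
from .families import FamilyId, has_aux
from .priors import PriorSpec, PriorTable, default_prior_table

__all__ = [
    "read_trial",
    "write_trial",
    "parse_prior",
    "format_prior",
    "RunConfig",
    "read_config",
    "write_config",
    "prior_table_to_config",
    "prior_table_from_config",
]

_COLUMNS = ("time", "status", "arm")


def read_trial(path, horizon: float | None = None) -> SurvivalDataset:
    """Read a delimited trial table (columns: time, status, arm).

    Malformed rows are reported with their (1-based, header-inclusive)
    line numbers; times must be positive, status and arm in {0, 1}.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = []
    time = pd.to_numeric(df["time"], errors="coerce")
    status = pd.to_numeric(df["status"], errors="coerce")
    arm = pd.to_numeric(df["arm"], errors="coerce")
    for idx in df.index:
        row_ok = (
            np.isfinite(time[idx])
            and time[idx] > 0
            and status[idx] in (0, 1)
            and arm[idx] in (0, 1)
        )
        if not row_ok:
            bad.append(idx + 2)  # +1 header, +1 one-based
    if bad:
        raise ValueError(f"{path}: malformed rows at lines {bad}")
    return SurvivalDataset(
        time.to_numpy(float), status.to_numpy(int), arm.to_numpy(int), horizon=horizon
    )


def write_trial(dataset: SurvivalDataset, path) -> None:
    """Write the canonical trial table; round-trips with read_trial."""
    dataset.to_dataframe().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------- priors


_PRIOR_RE = re.compile(
    r"^(?P<kind>S|N|LogN)\(\s*(?P<loc>[-+0-9.eE]+)\s*(?:,\s*(?P<scale>[-+0-9.eE]+)\s*)?\)"
    r"(?:\[\s*(?P<lower>[-+0-9.eE]+)\s*,\s*(?:inf|Inf)\s*\)?\]?)?$"
)


def parse_prior(text: str) -> PriorSpec:
    """Parse 'S(0)', 'N(0.3, 0.15)', 'N(0.3, 0.15)[0, inf)', 'LogN(0.62, 0.25)'."""
    m = _PRIOR_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse prior {text!r}")
    kind, loc = m.group("kind"), float(m.group("loc"))
    scale = float(m.group("scale")) if m.group("scale") else 0.0
    lower = m.group("lower")
    if kind == "S":
        return PriorSpec("spike", loc)
    if kind == "LogN":
        return PriorSpec("lognormal", loc, scale)
    if lower is not None:
        return PriorSpec("truncated_normal", loc, scale, lower_bound=float(lower))
    return PriorSpec("normal", loc, scale)


def format_prior(prior: PriorSpec) -> str:
    return str(prior)


def prior_table_to_config(table: PriorTable) -> dict[str, str]:
    out = {}
    for fam_id in FamilyId:
        out[f"prior.{fam_id.value}.alpha"] = format_prior(table.alpha[fam_id])
        if has_aux(fam_id):
            out[f"prior.{fam_id.value}.gamma"] = format_prior(table.gamma_aux[fam_id])
    out["prior.beta.null"] = format_prior(table.beta_null)
    out["prior.beta.alternative"] = format_prior(table.beta_alternative)
    out["prior.beta.estimation"] = format_prior(table.beta_estimation)
    return out


def prior_table_from_config(items: dict[str, str]) -> PriorTable:
    base = default_prior_table()
    alpha = dict(base.alpha)
    gamma = dict(base.gamma_aux)
    beta = {
        "null": base.beta_null,
        "alternative": base.beta_alternative,
        "estimation": base.beta_estimation,
    }
    for key, value in items.items():
        parts = key.split(".")
        if len(parts) != 3 or parts[0] != "prior":
            raise ValueError(f"unknown prior key {key!r}")
        _, which, param = parts
        spec = parse_prior(value)
        if which == "beta":
            if param not in beta:
                raise ValueError(f"unknown effect prior {param!r}")
            beta[param] = spec
        else:
            fam_id = FamilyId(which)
            if param == "alpha":
                alpha[fam_id] = spec
            elif param == "gamma":
                gamma[fam_id] = spec
            else:
                raise ValueError(f"unknown parameter {param!r} in {key!r}")
    return PriorTable(
        alpha=alpha,
        gamma_aux=gamma,
        beta_null=beta["null"],
        beta_alternative=beta["alternative"],
        beta_estimation=beta["estimation"],
    )


# ----------------------------------------------------------------- config


@dataclass
class RunConfig:
    """Plain-text key-value run configuration; defaults are the informed setup."""

    ensemble: str = "testing"
    method: str = "laplace"
    seed: int = 1
    n_total: int = 2070
    allocation: float = 0.5
    horizon: float = 1825.0
    reps: int = 500
    interval: float = 30.0
    design: str = "fixed"
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    output: str = "results"
    prior_overrides: dict[str, str] = field(default_factory=dict)

    def prior_table(self) -> PriorTable:
        return prior_table_from_config(self.prior_overrides)


_SCALAR_TYPES = {f.name: f.type for f in fields(RunConfig) if f.name != "prior_overrides"}


def read_config(path) -> RunConfig:
    """Read 'key = value' lines; '#' starts a comment; unknown keys are rejected."""
    cfg = RunConfig()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key.startswith("prior."):
                cfg.prior_overrides[key] = value
            elif key in _SCALAR_TYPES:
                current = getattr(cfg, key)
                caster = type(current)
                setattr(cfg, key, caster(value))
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    return cfg


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        for name in _SCALAR_TYPES:
            fh.write(f"{name} = {getattr(cfg, name)}\n")
        for key, value in cfg.prior_overrides.items():
            fh.write(f"{key} = {value}\n")
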