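"""Model specifications: one AFT family plus one prior set.

A :class:`ModelSpec` couples a parametric family with priors for the
intercept, the auxiliary parameter, and the treatment effect, together
with a prior model probability. A spike effect prior encodes the null
model (beta = 0); any proper effect prior encodes an alternative model.
"""

from __future__ import annotations

from dataclasses import dataclass

from .families import FamilyId, has_aux
from .priors import PriorSpec, PriorTable, default_prior_table

__all__ = ["ModelSpec", "testing_ensemble", "estimation_ensemble"]


@dataclass(frozen=True)
class ModelSpec:
    family: FamilyId
    alpha_prior: PriorSpec
    beta_prior: PriorSpec
    gamma_prior: PriorSpec | None = None
    prior_prob: float = 1.0

    def __post_init__(self) -> None:
        if has_aux(self.family) and self.gamma_prior is None:
            raise ValueError(f"{self.family} requires a gamma_aux prior")
        if not has_aux(self.family) and self.gamma_prior is not None:
            raise ValueError("exponential family has no auxiliary parameter")
        if not 0 < self.prior_prob <= 1:
            raise ValueError("prior_prob must lie in (0, 1]")

    @property
    def label(self) -> str:
        return "null" if self.beta_prior.is_spike else "alternative"

    @property
    def name(self) -> str:
        return f"{self.family.value}[{self.label}]"

    @property
    def is_null(self) -> bool:
        return self.beta_prior.is_spike


def _family_models(table: PriorTable, beta_prior: PriorSpec, prior_prob: float):
    out = []
    for fam in FamilyId:
        out.append(
            ModelSpec(
                family=fam,
                alpha_prior=table.alpha[fam],
                beta_prior=beta_prior,
                gamma_prior=table.gamma_aux.get(fam),
                prior_prob=prior_prob,
            )
        )
    return out


def testing_ensemble(table: PriorTable | None = None) -> list[ModelSpec]:
    """Ten models: five families x {null, alternative}, prior probability 1/10 each."""
    table = table or default_prior_table()
    return _family_models(table, table.beta_null, 0.10) + _family_models(
        table, table.beta_alternative, 0.10
    )


def estimation_ensemble(table: PriorTable | None = None) -> list[ModelSpec]:
    """Five alternative models with the estimation effect prior, probability 1/5 each."""
    table = table or default_prior_table()
    return _family_models(table, table.beta_estimation, 0.20)
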