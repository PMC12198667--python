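"""Model-object interface: :class:`BenchmarkDose` fits one endpoint and
returns :class:`BenchmarkDoseResults`.

The fit follows the full Bayesian benchmark-dose recipe: six candidate
mean curves (linear, power, Michaelis–Menten, Hill, exponential-3,
exponential-5) are each sampled by MCMC under flat data-scaled priors and
a lognormal error model; bridge sampling yields each model's marginal
likelihood; the better exponential variant joins the four algebraic models
in a five-model averaging set with equal prior weights of 0.2; per-draw
BMDs at the requested CES are pooled proportionally to the posterior model
weights; and the mixture median and 90% credible bounds give BMD, BMDL and
BMDU, which are then screened by the EFSA-style quality-control rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .averaging import ModelWeights, posterior_model_weights, select_exponential
from .bmd import (
    BmdEstimate,
    CesSpec,
    QcCriteria,
    QcVerdict,
    apply_qc,
    averaged_bmd,
    compute_bmd_draws,
)
from .data import DoseResponseDataset, EndpointResultRow, format_sig, summarize
from .evidence import EvidenceInstabilityError, bridge_sampling_evidence
from .mcmc import McmcSettings, ModelFit, run_mcmc
from .models import default_priors, get_model, log_likelihood

__all__ = ["BenchmarkDose", "BenchmarkDoseResults"]

# equal prior weights over the averaging set: 0.2 each for the usual
# five-model set after exponential-variant selection
ALGEBRAIC_MODELS = ("linear", "power", "michaelis_menten", "hill")


class BenchmarkDose:
    """Bayesian benchmark-dose model for one continuous endpoint.

    Parameters
    ----------
    dataset
        Individual-animal dose–response data.
    ces
        Critical effect size (signed); e.g. ``CesSpec.from_signed(+0.10)``.
    settings
        MCMC settings; the default is a single 30,000-iteration chain with
        a 50% warm-up rate.
    credible_level
        Width of the BMD credible interval (default 0.90, i.e. BMDL/BMDU
        at the 5th/95th percentiles).
    qc_criteria
        Defaults to the EFSA-style rules with the dose floor at one tenth
        of the lowest nonzero dose of `dataset`.
    models
        Candidate model names; defaults to all six.  When both exp3 and
        exp5 are present only the better-fitting variant (by marginal
        likelihood) enters the averaging set.
    """

    def __init__(
        self,
        dataset: DoseResponseDataset,
        ces: CesSpec | float,
        settings: McmcSettings | None = None,
        credible_level: float = 0.90,
        qc_criteria: QcCriteria | None = None,
        models: tuple[str, ...] | None = None,
    ):
        self.dataset = dataset
        self.ces = ces if isinstance(ces, CesSpec) else CesSpec.from_signed(float(ces))
        self.settings = settings or McmcSettings()
        self.credible_level = float(credible_level)
        self.qc_criteria = qc_criteria or QcCriteria.for_design(
            dataset.lowest_nonzero_dose
        )
        self.candidate_models = tuple(models) if models else ALGEBRAIC_MODELS + (
            "exp3",
            "exp5",
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        ces: CesSpec | float,
        study_id: str = "",
        endpoint_id: str = "",
        dose_col: str = "dose",
        response_col: str = "response",
        **kwargs,
    ) -> "BenchmarkDose":
        dataset = DoseResponseDataset(
            study_id=study_id,
            endpoint_id=endpoint_id,
            doses=df[dose_col].to_numpy(dtype=float),
            responses=df[response_col].to_numpy(dtype=float),
        )
        return cls(dataset, ces, **kwargs)

    # ------------------------------------------------------------------

    def fit(self, seed: int | None = None) -> "BenchmarkDoseResults":
        """Run the full six-model pipeline; reproducible under `seed`."""
        seed = self.settings.seed if seed is None else int(seed)
        dataset = self.dataset
        direction = self.ces.direction
        scale = dataset.max_dose
        events: list[str] = []

        model_objs = {
            name: get_model(name, direction=direction, dose_scale=scale)
            for name in self.candidate_models
        }

        # stable per-model seeds: order of this dict is fixed
        children = np.random.SeedSequence(seed).spawn(len(model_objs) + 1)
        fits: dict[str, ModelFit] = {}
        evidences: dict[str, float] = {}
        for (name, model), ss in zip(model_objs.items(), children[:-1]):
            sub_seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
            run_settings = McmcSettings(
                iterations=self.settings.iterations,
                warmup_fraction=self.settings.warmup_fraction,
                chains=self.settings.chains,
                seed=sub_seed,
            )
            fit = run_mcmc(dataset, model, run_settings)
            box = default_priors(model, dataset)
            log_prior_const = -box.log_volume

            def log_post(theta, _model=model, _box=box, _c=log_prior_const):
                if not _box.contains(theta):
                    return -math.inf
                return log_likelihood(dataset, _model, theta[:-1], theta[-1]) + _c

            try:
                fit.log_marginal_likelihood = bridge_sampling_evidence(
                    fit, log_post, seed=sub_seed + 1
                )
            except EvidenceInstabilityError as exc:
                events.append(f"{name}: evidence unstable, model dropped ({exc})")
                fit.log_marginal_likelihood = math.nan
            fits[name] = fit
            evidences[name] = fit.log_marginal_likelihood

        if "exp3" in evidences and "exp5" in evidences:
            exp_choice = select_exponential(evidences["exp3"], evidences["exp5"])
            events.append(f"exponential variant selected: {exp_choice}")
            dropped_exp = "exp3" if exp_choice == "exp5" else "exp5"
            averaging_set = [m for m in self.candidate_models if m != dropped_exp]
        else:
            exp_choice = next(
                (m for m in ("exp5", "exp3") if m in evidences), ""
            )
            averaging_set = list(self.candidate_models)

        weights = posterior_model_weights(
            {m: evidences[m] for m in averaging_set},
            {m: 1.0 / len(averaging_set) for m in averaging_set},
        )
        dropped = [m for m in averaging_set if m not in weights.posterior]
        for m in dropped:
            events.append(f"{m}: non-finite evidence, removed from averaging set")

        for m in weights.posterior:
            compute_bmd_draws(
                fits[m], model_objs[m], self.ces, max_dose=dataset.max_dose
            )
        bmd_seed = int(children[-1].generate_state(1)[0] & 0x7FFFFFFF)
        estimate = averaged_bmd(
            [fits[m] for m in weights.posterior],
            weights,
            self.ces,
            credible_level=self.credible_level,
            seed=bmd_seed,
        )
        qc = apply_qc(estimate, self.qc_criteria)

        return BenchmarkDoseResults(
            model=self,
            fits=fits,
            weights=weights,
            estimate=estimate,
            qc=qc,
            exponential_choice=exp_choice,
            seed=seed,
            events=events,
        )


@dataclass
class BenchmarkDoseResults:
    """Fitted results: per-model posteriors and evidence, posterior model
    weights, the averaged BMD estimate and its QC verdict."""

    model: BenchmarkDose
    fits: dict[str, ModelFit]
    weights: ModelWeights
    estimate: BmdEstimate
    qc: QcVerdict
    exponential_choice: str
    seed: int
    events: list[str] = field(default_factory=list)

    @property
    def bmdl(self) -> float:
        return self.estimate.bmdl

    @property
    def bmd(self) -> float:
        return self.estimate.bmd

    @property
    def bmdu(self) -> float:
        return self.estimate.bmdu

    def to_result_row(self) -> EndpointResultRow:
        return EndpointResultRow(
            study_id=self.model.dataset.study_id,
            endpoint_id=self.model.dataset.endpoint_id,
            ces_signed=self.model.ces.signed,
            bmdl=self.estimate.bmdl,
            bmd=self.estimate.bmd,
            bmdu=self.estimate.bmdu,
            qc_pass=self.qc.passed,
            model_weights=dict(self.weights.posterior),
            qc_reasons=self.qc.reasons,
        )

    def summary(self) -> str:
        ds = self.model.dataset
        est = self.estimate
        lines = []
        lines.append("Bayesian benchmark-dose model averaging")
        lines.append("=" * 55)
        lines.append(f"study / endpoint : {ds.study_id} / {ds.endpoint_id}")
        lines.append(
            f"observations     : {ds.n_obs} animals, "
            f"{ds.distinct_doses.size} dose groups (top {format_sig(ds.max_dose)})"
        )
        lines.append(
            f"CES              : {self.model.ces.signed:+.0%} of background "
            f"({'increasing' if self.model.ces.direction > 0 else 'decreasing'})"
        )
        lines.append(
            f"MCMC             : {self.model.settings.iterations} iterations, "
            f"{self.model.settings.warmup_fraction:.0%} warm-up, seed {self.seed}"
        )
        lines.append("-" * 55)
        lines.append(f"{'model':<18}{'log ML':>12}{'weight':>10}")
        for m, fit in self.fits.items():
            w = self.weights.posterior.get(m)
            wtxt = f"{w:.3f}" if w is not None else "  --"
            ml = fit.log_marginal_likelihood
            mltxt = f"{ml:.2f}" if math.isfinite(ml) else "NA"
            mark = "*" if m == self.exponential_choice and m.startswith("exp") else ""
            lines.append(f"{m + mark:<18}{mltxt:>12}{wtxt:>10}")
        lines.append("-" * 55)
        pct = est.credible_level
        lines.append(
            f"BMDL / BMD / BMDU ({pct:.0%} CrI): "
            f"{format_sig(est.bmdl)} / {format_sig(est.bmd)} / {format_sig(est.bmdu)}"
        )
        row = self.to_result_row()
        lines.append(
            f"BMD/BMDL = {row.ratio_bmd_bmdl:.1f}  BMDU/BMDL = {row.ratio_bmdu_bmdl:.1f}"
            if np.isfinite(row.ratio_bmd_bmdl)
            else "BMD/BMDL = NA  BMDU/BMDL = NA"
        )
        lines.append(
            f"valid draws      : {est.n_valid_draws}/{est.n_total_draws}"
            + ("  [direction-inconsistent]" if est.direction_inconsistent else "")
        )
        if est.clamped:
            lines.append("BMDL clamped to 0 (lower credible bound was <= 0)")
        verdict = "PASS" if self.qc.passed else "FAIL (" + ", ".join(self.qc.reasons) + ")"
        lines.append(f"QC verdict       : {verdict}")
        return "\n".join(lines)

    def plot_fit(self, ax=None, n_curves: int = 0):
        """Plot group geometric means and the weighted posterior-median
        curves of the averaging set (optionally `n_curves` posterior draws
        per model, thinned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ds = self.model.dataset
        for s in summarize(ds):
            ax.plot(s.dose, s.mean, "ko", ms=4)
        dmax = ds.max_dose
        grid = np.linspace(0.0, dmax, 200)
        for m, w in self.weights.posterior.items():
            fit = self.fits[m]
            mod = get_model(m, direction=self.model.ces.direction, dose_scale=dmax)
            med = np.median(fit.draws[:, :-1], axis=0)
            ax.plot(grid, mod.mean(med, grid), label=f"{m} (w={w:.2f})", alpha=0.8)
            if n_curves:
                idx = np.linspace(0, fit.n_draws - 1, n_curves).astype(int)
                for i in idx:
                    ax.plot(grid, mod.mean(fit.draws[i, :-1], grid), lw=0.3, alpha=0.2)
        ax.set_xlabel("dose (mg/kg bw/d)")
        ax.set_ylabel(ds.units or "response")
        ax.set_title(f"{ds.study_id} / {ds.endpoint_id}")
        ax.legend(fontsize=8)
        return ax
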