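"""Ground-truthed synthetic LC-HRMS tracing experiments.

The generator composes the forward model the analysis assumes, in order:

1. per group, true MIDs are the convex combination of the regime template MIDs
   (labeling engine) under the group's pathway mixture and tracer enrichment;
2. natural-abundance convolution at ``p13`` (tracer impurity enters upstream
   as an i.i.d. per-carbon labeling probability on the tracer MID);
3. per-sample global scale factors (log-normal — instrument response and
   loading vary multiplicatively between runs);
4. per-peak multiplicative log-normal noise with a stated coefficient of
   variation (chromatographic areas are positive and heteroscedastic, which
   rules out additive Gaussian noise).

Defaults mirror the study conditions: two groups (uninfected/infected) of
five biological replicates, tracer media of 0.5 mM 13C6 glucose or 5 mM 13C12
trehalose, with the infected group shifted toward cyclic-PPP usage.  All
randomness flows from one seeded :func:`numpy.random.default_rng` (PCG64),
recorded in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .carbon_atlas import default_network
from .isotope_correction import DEFAULT_P13, build_correction_matrix, apply_natural_abundance
from .label_engine import (
    REGIMES,
    REPORTED_METABOLITES,
    glucose_tracer,
    template_mids,
    trehalose_tracer,
)

#: peak-area scales per reported metabolite (arbitrary area units; order-of-
#: magnitude placeholders for HILIC-HRMS pool sizes, not measured values)
DEFAULT_BASELINE = {
    "G6P": 1.0e6,
    "F6P": 8.0e5,
    "Ru5P": 2.0e5,
    "S7P": 1.0e5,
    "GAP": 3.0e5,
    "lactate": 2.0e6,
}


@dataclass(frozen=True)
class GroupSpec:
    label: str
    mixture: dict[str, float]
    enrichment: float

    def __post_init__(self) -> None:
        unknown = set(self.mixture) - set(REGIMES)
        if unknown:
            raise ValueError(f"unknown regimes in mixture: {sorted(unknown)}")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9 or any(w < 0 for w in self.mixture.values()):
            raise ValueError(f"{self.label}: mixture must be nonnegative and sum to 1")


def default_groups() -> tuple[GroupSpec, ...]:
    """Uninfected vs infected: infection raises tracer uptake and cyclic-PPP weight."""
    return (
        GroupSpec(
            "uninfected",
            {"direct_glycolysis": 0.55, "oxppp_single_pass": 0.20,
             "cyclic_ppp": 0.10, "nonox_ppp": 0.15},
            enrichment=0.4,
        ),
        GroupSpec(
            "infected",
            {"direct_glycolysis": 0.35, "oxppp_single_pass": 0.20,
             "cyclic_ppp": 0.30, "nonox_ppp": 0.15},
            enrichment=0.6,
        ),
    )


@dataclass
class SyntheticConfig:
    groups: tuple[GroupSpec, ...] = field(default_factory=default_groups)
    n_replicates: int = 5
    tracer_setup: str = "glucose_m6"  # or "trehalose_m12"
    glucose_mm: float = 0.5
    trehalose_mm: float = 5.0
    rounds: int = 2
    p13: float = DEFAULT_P13
    purity: float = 1.0
    scale_sigma: float = 0.25  # log-sd of per-sample global scale factors
    noise_cv: float = 0.10  # per-peak multiplicative noise CV
    baseline: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.tracer_setup not in ("glucose_m6", "trehalose_m12"):
            raise ValueError(f"unknown tracer setup {self.tracer_setup!r}")
        if min(self.scale_sigma, self.noise_cv) < 0:
            raise ValueError("variance parameters must be >= 0")

    def tracer(self, net) -> dict:
        if self.tracer_setup == "glucose_m6":
            return glucose_tracer(net, self.purity)
        return trehalose_tracer(net, self.purity)


@dataclass
class GroundTruth:
    true_mids: dict[str, dict[str, tuple[float, ...]]]  # group -> metabolite -> MID
    true_weights: dict[str, dict[str, float]]  # group -> regime -> weight
    scale_factors: dict[str, float]  # sample_id -> factor
    metadata: dict


def generate_experiment(cfg: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one tracing experiment; returns (peak-area table, ground truth)."""
    net = default_network()
    rng = np.random.default_rng(cfg.seed)
    tracer = cfg.tracer(net)

    true_mids: dict[str, dict[str, tuple[float, ...]]] = {}
    true_weights: dict[str, dict[str, float]] = {}
    scale_factors: dict[str, float] = {}
    rows: list[dict] = []

    noise_sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))
    for group in cfg.groups:
        templates = template_mids(net, tracer, group.enrichment, cfg.rounds)
        weights = np.array([group.mixture.get(r, 0.0) for r in templates.columns])
        mixed = templates.to_numpy() @ weights  # stacked true fractions
        mixed_s = pd.Series(mixed, index=templates.index)

        true_weights[group.label] = {r: group.mixture.get(r, 0.0) for r in REGIMES}
        true_mids[group.label] = {
            met: tuple(mixed_s.loc[met].to_numpy())
            for met in REPORTED_METABOLITES
        }

        observed: dict[str, np.ndarray] = {}
        for met in REPORTED_METABOLITES:
            n = net.metabolite(met).n_carbons
            matrix = build_correction_matrix(n, cfg.p13)
            observed[met] = apply_natural_abundance(
                mixed_s.loc[met].to_numpy(), matrix
            )

        for rep in range(cfg.n_replicates):
            sample_id = f"{group.label}_{rep + 1}"
            scale = float(np.exp(rng.normal(0.0, cfg.scale_sigma))) if cfg.scale_sigma else 1.0
            scale_factors[sample_id] = scale
            for met in REPORTED_METABOLITES:
                base = cfg.baseline.get(met, 1.0e6)
                for shift, frac in enumerate(observed[met]):
                    if cfg.noise_cv > 0:
                        noise = float(np.exp(
                            rng.normal(-0.5 * noise_sigma**2, noise_sigma)
                        ))
                    else:
                        noise = 1.0
                    rows.append({
                        "sample_id": sample_id,
                        "group": group.label,
                        "metabolite": met,
                        "mass_shift": shift,
                        "peak_area": base * scale * frac * noise,
                        "stage": "raw",
                    })

    table = pd.DataFrame(rows)
    truth = GroundTruth(
        true_mids=true_mids,
        true_weights=true_weights,
        scale_factors=scale_factors,
        metadata={
            "rng": "numpy.random.default_rng/PCG64",
            "seed": cfg.seed,
            "tracer_setup": cfg.tracer_setup,
            "glucose_mm": cfg.glucose_mm,
            "trehalose_mm": cfg.trehalose_mm,
            "p13": cfg.p13,
            "purity": cfg.purity,
            "rounds": cfg.rounds,
            "noise_cv": cfg.noise_cv,
            "scale_sigma": cfg.scale_sigma,
        },
    )
    return table, truth


def end_to_end_recovery(cfg: SyntheticConfig) -> dict:
    """Generate -> normalize -> correct -> fractions -> fit; report weight errors.

    Corrected fractions are averaged across replicates within each group
    before deconvolution against templates computed at the group's (known)
    enrichment.  Returns recovered weights and the max absolute weight error
    per group.
    """
    from .infer_stats import fit_mixture
    from .quantify import correct_fractions_table, fractions_table, normalize_table

    net = default_network()
    table, truth = generate_experiment(cfg)
    reference = f"{cfg.groups[0].label}_1"
    normalized, factors = normalize_table(table, reference)
    fractions = fractions_table(normalized, net)
    corrected = correct_fractions_table(fractions, cfg.p13)

    tracer = cfg.tracer(net)
    report: dict = {
        "groups": {},
        "normalization_factors": {f.sample_id: f.factor for f in factors},
        "seed": cfg.seed,
    }
    for group in cfg.groups:
        templates = template_mids(net, tracer, group.enrichment, cfg.rounds)
        sub = corrected[corrected["group"] == group.label]
        mean_frac = (
            sub.groupby(["metabolite", "mass_shift"])["corrected_fraction"]
            .mean()
            .reindex(templates.index, fill_value=0.0)
        )
        mixture = fit_mixture(mean_frac, templates)
        errors = {
            r: abs(mixture.weights.get(r, 0.0) - truth.true_weights[group.label][r])
            for r in REGIMES
        }
        report["groups"][group.label] = {
            "true_weights": truth.true_weights[group.label],
            "recovered_weights": mixture.weights,
            "residual": mixture.residual,
            "max_weight_error": max(errors.values()),
        }
    report["max_weight_error"] = max(
        g["max_weight_error"] for g in report["groups"].values()
    )
    return report


def config_to_dict(cfg: SyntheticConfig) -> dict:
    """JSON-ready echo of a config (for the reproducibility bundle)."""
    d = asdict(cfg)
    d["groups"] = [asdict(g) for g in cfg.groups]
    return d
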