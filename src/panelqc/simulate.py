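"""Synthetic instrument-like runs with known ground-truth QC status.

Each sample's library is built from exact control budgets plus stochastic
gene counts: the configured positive and negative control fractions are
converted to read budgets (rounded, then split multinomially within each
control set) and the remaining reads are distributed over genes in
proportion to negative-binomial draws around a shared lognormal expression
profile.  Budgets are exact so the truth flags computed from the configured
fractions are reproduced by the QC itself; gene counts are stochastic so
dispersion-sensitive downstream steps (VST, PCA) see realistic data.

Baseline negative-control fractions vary smoothly across samples (a narrow
linspace) rather than being identical: with identical fractions the
deviances would be pure rounding noise and the scale-free +/-k*SD band
could flag an arbitrary sample.  A linear spread keeps every deviance
within 2 standard deviations by construction (max |delta|/SD ~ 1.53 for a
linspace of 8+ points) while exercising the band with non-zero deviances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_counts_table, write_instrument_export
from .matrix import ExpressionMatrix, PanelQCError
from .qc import (
    Flag,
    QCThresholds,
    combine_flags,
    flag_negative,
    flag_positive,
    negative_deviance,
    MIN_SAMPLES_FOR_BAND,
)

SCENARIOS = (
    "clean_run",
    "single_pos_failure",
    "single_neg_contamination",
    "alert_only",
    "complete_run_failure",
)

TRUTH_COLUMNS = ["sample_id", "pos_fraction", "neg_fraction", "pos_flag", "neg_flag", "overall_flag"]


@dataclass(frozen=True)
class SyntheticRunConfig:
    """Parameters of one synthetic run.

    ``pos_fraction`` / ``neg_fraction`` may be a scalar (applied to every
    sample) or a per-sample sequence.  ``library_size`` is the mean library;
    individual libraries get lognormal jitter with ``library_log_sd`` on the
    log scale.  ``dispersion`` is the NB dispersion alpha of the gene counts
    (variance mu + alpha*mu^2).
    """

    n_samples: int = 16
    n_genes: int = 200
    library_size: float = 2_000_000.0
    library_log_sd: float = 0.25
    dispersion: float = 0.3
    pos_fraction: float | tuple[float, ...] = 0.02
    neg_fraction: float | tuple[float, ...] = 0.005
    n_pos_probes: int = 4
    n_neg_probes: int = 4
    seed: int = 0
    scenario: str = "custom"

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise PanelQCError("need at least 1 sample and 1 gene")
        if self.n_pos_probes < 1 or self.n_neg_probes < 1:
            raise PanelQCError("need at least 1 probe in each control set")
        if self.dispersion < 0:
            raise PanelQCError("dispersion must be >= 0")
        for name in ("pos_fraction", "neg_fraction"):
            value = getattr(self, name)
            if np.isscalar(value):
                value = (float(value),) * self.n_samples
            else:
                value = tuple(float(v) for v in value)
                if len(value) != self.n_samples:
                    raise PanelQCError(
                        f"{name} has {len(value)} entries for {self.n_samples} samples"
                    )
            object.__setattr__(self, name, value)
        for fp, fn in zip(self.pos_fraction, self.neg_fraction):
            if fp < 0 or fn < 0 or fp + fn >= 1.0:
                raise PanelQCError(
                    f"infeasible control fractions pos={fp}, neg={fn} "
                    "(need non-negative, pos + neg < 1)"
                )

    @property
    def probe_ids(self) -> tuple[str, ...]:
        pos = tuple(f"POS{i + 1}" for i in range(self.n_pos_probes))
        neg = tuple(f"ANT{i + 1}" for i in range(self.n_neg_probes))
        genes = tuple(f"GENE{i + 1:04d}" for i in range(self.n_genes))
        return pos + neg + genes

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1:02d}" for i in range(self.n_samples))


def truth_flags(config: SyntheticRunConfig, thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """Expected QC flags implied by the configured control fractions.

    Positive and fraction flags follow directly from the fractions; the
    deviance flag is derived from the expected negative-control mean CPM,
    ``neg_fraction * 1e6 / n_neg_probes``, which the exact read budgets make
    deterministic up to integer rounding.
    """
    pos_pct = 100.0 * np.asarray(config.pos_fraction)
    neg_pct = 100.0 * np.asarray(config.neg_fraction)
    exp_cpm = np.asarray(config.neg_fraction) * 1e6 / config.n_neg_probes
    delta = negative_deviance(exp_cpm)
    n = config.n_samples
    applied = n >= MIN_SAMPLES_FOR_BAND
    sd = float(np.std(delta, ddof=1)) if n >= 2 else 0.0
    rows = []
    for i, sample in enumerate(config.sample_ids):
        pflag = flag_positive(float(pos_pct[i]), thresholds)
        nflag = flag_negative(
            float(neg_pct[i]), float(delta[i]), sd, thresholds, deviance_filter_applied=applied
        )
        rows.append(
            {
                "sample_id": sample,
                "pos_fraction": config.pos_fraction[i],
                "neg_fraction": config.neg_fraction[i],
                "pos_flag": pflag.value,
                "neg_flag": nflag.value,
                "overall_flag": combine_flags(pflag, nflag).value,
            }
        )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def generate_run(
    config: SyntheticRunConfig,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate one run and its ground-truth flag table.

    Deterministic: the same config (including seed) yields a bit-identical
    matrix.
    """
    rng = np.random.default_rng(config.seed)
    n_pos, n_neg = config.n_pos_probes, config.n_neg_probes
    counts = np.zeros((n_pos + n_neg + config.n_genes, config.n_samples), dtype=np.int64)

    # shared expression profile across the run; wide lognormal for realism
    base = rng.lognormal(mean=2.0, sigma=1.5, size=config.n_genes)

    mu_log = np.log(config.library_size) - config.library_log_sd**2 / 2.0
    for j in range(config.n_samples):
        lib = max(1, int(round(rng.lognormal(mu_log, config.library_log_sd))))
        pos_budget = int(round(config.pos_fraction[j] * lib))
        neg_budget = int(round(config.neg_fraction[j] * lib))
        rest = lib - pos_budget - neg_budget
        if rest < 0:
            raise PanelQCError(f"infeasible fractions for sample {config.sample_ids[j]}")
        counts[:n_pos, j] = rng.multinomial(pos_budget, np.full(n_pos, 1.0 / n_pos))
        counts[n_pos : n_pos + n_neg, j] = rng.multinomial(
            neg_budget, np.full(n_neg, 1.0 / n_neg)
        )
        mu = base / base.sum() * rest
        if config.dispersion > 0:
            lam = rng.gamma(1.0 / config.dispersion, mu * config.dispersion)
        else:
            lam = mu
        draws = rng.poisson(lam)
        weights = draws if draws.sum() > 0 else base
        counts[n_pos + n_neg :, j] = rng.multinomial(rest, weights / weights.sum())

    matrix = ExpressionMatrix(
        probe_ids=config.probe_ids, sample_ids=config.sample_ids, counts=counts
    )
    return matrix, truth_flags(config, thresholds)


def scenario_presets(name: str, seed: int = 0, n_samples: int | None = None) -> SyntheticRunConfig:
    """Documented parameterizations of the named contamination scenarios.

    - ``clean_run``: 16 samples, spike-in fractions spread over 1-4% (the
      good-quality range), background 0.4-0.6%.
    - ``single_pos_failure``: 8 samples, first sample's spike-in fraction
      0.50 (FAIL), others 2%.
    - ``single_neg_contamination``: 8 samples, first sample's background
      fraction 0.15 (FAIL), others baseline.
    - ``alert_only``: 8 samples, first sample's spike-in fraction 0.15
      (ALERT band), none above the FAIL threshold.
    - ``complete_run_failure``: 8 samples, background fractions 18-22% —
      every sample fails the fraction rule while all deviances stay inside
      the +/-2*SD band.

    All fractions sit at least 2 percentage points away from the decision
    thresholds so sampling noise cannot flip a flag.
    """
    if name not in SCENARIOS:
        raise PanelQCError(f"unknown scenario {name!r}; choose from {SCENARIOS}")

    def lin(lo: float, hi: float, n: int) -> tuple[float, ...]:
        return tuple(np.linspace(lo, hi, n))

    if name == "clean_run":
        n = n_samples or 16
        return SyntheticRunConfig(
            n_samples=n,
            pos_fraction=lin(0.01, 0.04, n),
            neg_fraction=lin(0.004, 0.006, n),
            seed=seed,
            scenario=name,
        )
    n = n_samples or 8
    baseline_neg = lin(0.004, 0.006, n)
    if name == "single_pos_failure":
        pos = (0.50,) + (0.02,) * (n - 1)
        return SyntheticRunConfig(
            n_samples=n, pos_fraction=pos, neg_fraction=baseline_neg, seed=seed, scenario=name
        )
    if name == "single_neg_contamination":
        neg = (0.15,) + tuple(lin(0.004, 0.006, n - 1))
        return SyntheticRunConfig(
            n_samples=n, pos_fraction=0.02, neg_fraction=neg, seed=seed, scenario=name
        )
    if name == "alert_only":
        pos = (0.15,) + (0.02,) * (n - 1)
        return SyntheticRunConfig(
            n_samples=n, pos_fraction=pos, neg_fraction=baseline_neg, seed=seed, scenario=name
        )
    # complete_run_failure
    return SyntheticRunConfig(
        n_samples=n,
        pos_fraction=0.02,
        neg_fraction=lin(0.18, 0.22, n),
        seed=seed,
        scenario=name,
    )


def write_run_fixtures(config: SyntheticRunConfig, outdir, stem: str = "run") -> dict[str, Path]:
    """Write a generated run in both input dialects plus its truth-flag table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_run(config)
    paths = {
        "delimited": outdir / f"{stem}_counts.csv",
        "instrument": outdir / f"{stem}_instrument.csv",
        "truth": outdir / f"{stem}_truth.csv",
    }
    write_counts_table(matrix, paths["delimited"])
    write_instrument_export(matrix, paths["instrument"])
    truth.to_csv(paths["truth"], index=False)
    return paths
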