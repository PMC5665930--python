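"""Seeded generators for every input table the pipeline consumes.

All generators are pure functions of their spec (including its seed):
calling one twice with the same spec returns identical tables. Each
generator also returns a "truth" dict recording the planted structure
(group labels, differential features, peripheral enzymes) so that
downstream recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Default incubation timepoints in minutes.
DEFAULT_TIMEPOINTS: tuple[float, ...] = (0.0, 1.5, 3.0)

#: Printed percent-turnover ranges of the low / high metabolizer groups.
LOW_RANGE: tuple[float, float] = (0.04, 8.72)
HIGH_RANGE: tuple[float, float] = (26.46, 77.11)

#: Initial substrate concentration (µM) used in the incubation protocol.
SUBSTRATE_INITIAL_UM = 100.0


def _sample_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated turnover cohort.

    ``low_range``/``high_range`` are percent-of-substrate turnover ranges;
    each individual's endpoint turnover fraction is drawn uniformly from
    their group's range. A degenerate range ``(x, x)`` pins the draw to
    ``x`` exactly, which is how boundary cases are generated.
    """

    n_low: int = 16
    n_high: int = 4
    low_range: tuple[float, float] = LOW_RANGE
    high_range: tuple[float, float] = HIGH_RANGE
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0
    substrate_initial: float = SUBSTRATE_INITIAL_UM
    istd_area: float = 1.0e5
    response_slope: float = 0.02  # peak-area ratio per µM, shared true curve

    def __post_init__(self) -> None:
        if self.n_low < 0 or self.n_high < 0 or self.n_individuals < 1:
            raise ValidationError("cohort must contain at least one individual")
        for name, (lo, hi) in (("low_range", self.low_range), ("high_range", self.high_range)):
            if not (0 <= lo <= hi <= 100):
                raise ValidationError(f"{name} must satisfy 0 <= min <= max <= 100")
        if self.n_low and self.n_high and self.low_range[1] >= self.high_range[0]:
            raise ValidationError("low_range and high_range must not overlap")
        if len(self.timepoints) == 0:
            raise ValidationError("timepoints must be non-empty")
        if sorted(self.timepoints) != list(self.timepoints) or self.timepoints[0] != 0:
            raise ValidationError("timepoints must be sorted and start at 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.substrate_initial <= 0 or self.istd_area <= 0 or self.response_slope <= 0:
            raise ValidationError("substrate_initial, istd_area and response_slope must be > 0")

    @property
    def n_individuals(self) -> int:
        return self.n_low + self.n_high


def simulate_turnover(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a per-replicate peak-area time course for a cohort.

    The analyte (deconjugated metabolite) concentration rises linearly in
    expectation from 0 at t=0 to ``f * substrate_initial`` at the final
    timepoint, where ``f`` is the individual's endpoint turnover fraction;
    the substrate falls by the same amount. Peak areas follow a shared
    linear response (``response_slope`` area-ratio per µM against a
    constant internal standard) with independent multiplicative log-normal
    noise of coefficient of variation ``noise_cv`` per measurement.

    Returns
    -------
    (table, truth)
        ``table`` has one row per individual × timepoint × replicate with
        columns ``individual, timepoint_min, replicate, area_sn38,
        area_sn38g, area_istd``. ``truth`` records the planted group label
        and endpoint percent turnover per individual.
    """
    rng = np.random.default_rng(spec.seed)
    individuals = _sample_ids(spec.n_individuals)
    labels = ["low"] * spec.n_low + ["high"] * spec.n_high
    percents = np.concatenate(
        [
            rng.uniform(*spec.low_range, size=spec.n_low),
            rng.uniform(*spec.high_range, size=spec.n_high),
        ]
    )
    t = np.asarray(spec.timepoints, dtype=float)
    t_final = t[-1]
    frac_of_final = t / t_final if t_final > 0 else np.zeros_like(t)

    rows: list[dict] = []
    for ind, pct in zip(individuals, percents):
        conc_analyte = (pct / 100.0) * spec.substrate_initial * frac_of_final
        conc_substrate = spec.substrate_initial - conc_analyte
        for ti, (ca, cs) in enumerate(zip(conc_analyte, conc_substrate)):
            noise = _lognormal_noise(rng, spec.noise_cv, (spec.replicates, 3))
            for rep in range(spec.replicates):
                rows.append(
                    {
                        "individual": ind,
                        "timepoint_min": t[ti],
                        "replicate": rep + 1,
                        "area_sn38": ca * spec.response_slope * spec.istd_area * noise[rep, 0],
                        "area_sn38g": cs * spec.response_slope * spec.istd_area * noise[rep, 1],
                        "area_istd": spec.istd_area * noise[rep, 2],
                    }
                )
    table = pd.DataFrame(rows)
    truth = {
        "labels": dict(zip(individuals, labels)),
        "percent_turnover": dict(zip(individuals, percents.tolist())),
        "substrate_initial": spec.substrate_initial,
        "response_slope": spec.response_slope,
    }
    return table, truth


def true_calibration_table(spec: CohortSpec, metabolite: str = "SN-38") -> pd.DataFrame:
    """Noiseless calibration table matching the response used by
    :func:`simulate_turnover`, for exact round-trip quantitation."""
    levels = [0.0, 1.0, 10.0, 50.0, 100.0]
    return simulate_calibration(
        levels, slope=spec.response_slope, intercept=0.0, noise_sd=0.0, seed=0,
        metabolite=metabolite,
    )


def simulate_calibration(
    levels: Sequence[float],
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int = 0,
    replicates: int = 1,
    metabolite: str = "SN-38",
) -> pd.DataFrame:
    """Simulate a calibration table of peak-area ratio vs concentration.

    ``ratio = slope * concentration + intercept + N(0, noise_sd)`` per
    level × replicate. Requires at least two distinct levels.
    """
    levels = [float(x) for x in levels]
    if len(set(levels)) < 2:
        raise ValidationError("calibration needs >= 2 distinct concentration levels")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for level in levels:
        for _ in range(replicates):
            ratio = slope * level + intercept
            if noise_sd > 0:
                ratio += rng.normal(0.0, noise_sd)
            rows.append({"metabolite": metabolite, "concentration_uM": level, "area_ratio": ratio})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FeatureTableSpec:
    """Parameters of a simulated feature-abundance matrix.

    ``group_labels`` holds one 0/1 flag per sample (1 = high group);
    ``planted`` lists ``(feature_index, fold_change)`` effects applied
    multiplicatively to the high-group samples.
    """

    n_features: int
    group_labels: tuple[int, ...]
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    planted: tuple[tuple[int, float], ...] = ()
    seed: int = 0
    category: str = "KO"

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValidationError("n_features must be >= 1")
        if len(self.group_labels) < 1:
            raise ValidationError("group_labels must be non-empty")
        if any(g not in (0, 1) for g in self.group_labels):
            raise ValidationError("group_labels must be binary 0/1")
        if self.baseline_log_sd < 0:
            raise ValidationError("baseline_log_sd must be >= 0")
        for fid, fold in self.planted:
            if not (0 <= fid < self.n_features):
                raise ValidationError(f"planted feature id {fid} out of range")
            if fold <= 0:
                raise ValidationError("planted fold_change must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.group_labels)


def feature_ids(spec: FeatureTableSpec) -> list[str]:
    width = max(3, len(str(spec.n_features)))
    return [f"{spec.category}{i:0{width}d}" for i in range(spec.n_features)]


def simulate_feature_table(
    spec: FeatureTableSpec,
    sample_ids: Sequence[str] | None = None,
    ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a features × samples abundance matrix.

    Every entry is an independent log-normal draw,
    ``exp(N(baseline_log_mean, baseline_log_sd))``; planted features are
    multiplied by their fold change in high-group samples. All values are
    strictly positive. ``ids`` overrides the generated feature ids (e.g.
    to match the enzyme ids of a simulated reaction annotation).
    """
    rng = np.random.default_rng(spec.seed)
    if sample_ids is None:
        sample_ids = _sample_ids(spec.n_samples)
    elif len(sample_ids) != spec.n_samples:
        raise ValidationError("sample_ids length must match group_labels")
    mat = np.exp(
        rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=(spec.n_features, spec.n_samples))
    )
    high = np.asarray(spec.group_labels, dtype=bool)
    for fid, fold in spec.planted:
        mat[fid, high] *= fold
    if ids is not None:
        if len(ids) != spec.n_features:
            raise ValidationError("ids length must equal n_features")
        fids = list(ids)
    else:
        fids = feature_ids(spec)
    table = pd.DataFrame(mat, index=pd.Index(fids, name="feature_id"), columns=list(sample_ids))
    truth = {
        "planted": {fids[fid]: fold for fid, fold in spec.planted},
        "labels": {
            s: ("high" if g else "low") for s, g in zip(sample_ids, spec.group_labels)
        },
        "category": spec.category,
    }
    return table, truth


@dataclass(frozen=True)
class ReactionSpec:
    """Parameters of a simulated enzyme/compound reaction annotation.

    ``n_chains`` linear chains of ``chain_length`` enzymes are generated
    (enzyme i's product is enzyme i+1's substrate), then ``cross_links``
    extra random product→substrate sharings are added between non-adjacent
    enzymes. ``n_currency`` ubiquitous compounds are attached to every
    enzyme's substrate and product sets; a downstream blacklist of those
    compounds restores the chain topology. Chain endpoints are recorded as
    ground-truth peripheral enzymes.
    """

    n_chains: int = 4
    chain_length: int = 5
    cross_links: int = 0
    n_currency: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")
        if self.chain_length < 3:
            raise ValidationError("chain_length must be >= 3")
        if self.cross_links < 0 or self.n_currency < 0:
            raise ValidationError("cross_links and n_currency must be >= 0")

    @property
    def n_enzymes(self) -> int:
        return self.n_chains * self.chain_length


def currency_compound_ids(spec: ReactionSpec) -> list[str]:
    return [f"CUR{i:02d}" for i in range(spec.n_currency)]


def enzyme_ids(spec: ReactionSpec) -> list[str]:
    """Enzyme ids of :func:`simulate_reactions`, in table order."""
    return [
        f"K{c:02d}_{j:02d}"
        for c in range(spec.n_chains)
        for j in range(spec.chain_length)
    ]


def peripheral_indices(spec: ReactionSpec) -> list[int]:
    """Positions of the ground-truth peripheral (chain-end) enzymes within
    :func:`enzyme_ids`, usable as planted feature indices."""
    ids = enzyme_ids(spec)
    ends = {
        f"K{c:02d}_{j:02d}"
        for c in range(spec.n_chains)
        for j in (0, spec.chain_length - 1)
    }
    return [i for i, e in enumerate(ids) if e in ends]


def simulate_reactions(spec: ReactionSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a reaction annotation table (enzyme → substrates/products)."""
    rng = np.random.default_rng(spec.seed)
    currency = currency_compound_ids(spec)
    rows: list[dict] = []
    peripheral: list[str] = []
    substrates: dict[str, set[str]] = {}
    products: dict[str, set[str]] = {}
    for c in range(spec.n_chains):
        for j in range(spec.chain_length):
            enz = f"K{c:02d}_{j:02d}"
            substrates[enz] = {f"C{c:02d}_{j:02d}"}
            products[enz] = {f"C{c:02d}_{j + 1:02d}"}
            if j == 0 or j == spec.chain_length - 1:
                peripheral.append(enz)
    enzymes = sorted(substrates)
    # extra product->substrate sharings between random non-adjacent enzyme pairs
    for k in range(spec.cross_links):
        u, v = rng.choice(len(enzymes), size=2, replace=False)
        compound = f"X{k:03d}"
        products[enzymes[u]].add(compound)
        substrates[enzymes[v]].add(compound)
    for enz in enzymes:
        subs = sorted(substrates[enz]) + currency
        prods = sorted(products[enz]) + currency
        rows.append(
            {"enzyme_id": enz, "substrates": ";".join(subs), "products": ";".join(prods)}
        )
    table = pd.DataFrame(rows)
    truth = {
        "peripheral": peripheral,
        "currency_compounds": currency,
        "chains": {
            f"chain{c:02d}": [f"K{c:02d}_{j:02d}" for j in range(spec.chain_length)]
            for c in range(spec.n_chains)
        },
    }
    return table, truth
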