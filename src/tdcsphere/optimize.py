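"""Montage evaluation, ranking, per-model optima and conductivity sensitivity.

For every candidate montage the pipeline places the electrodes on each model
of the population, solves the volume-conduction problem, samples |E| on the
cortical surface and averages it over the four M1/SMA ROIs.  The
optimization objective is the population mean of the unweighted four-ROI
average; per-model optima are counted as a robustness diagnostic, and the
whole analysis is repeated under perturbed bone (±50%) and CSF (±10%)
conductivities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cortex import default_rois, roi_means_for_model
from .fem import build_source, compute_efield, solve_potential
from .montage import ElectrodeSpec, MontageSpec, place_electrodes
from .phantom import TissueConductivityTable, VoxelModel, conductivity_table

log = logging.getLogger(__name__)

ROI_ORDER = ("M1_left", "M1_right", "SMA_left", "SMA_right")


@dataclass
class SolverSettings:
    """Bundled pipeline settings: solver tolerance, sampling density and the
    electrode build."""

    tol: float = 1e-6
    maxiter: int = 10000
    n_surface_points: int = 10000
    sampling_depth_mm: float = 1.0
    electrode: ElectrodeSpec = field(default_factory=ElectrodeSpec)


@dataclass
class MontageEvaluation:
    """Per-model ROI means for one montage plus population mean ± SD.

    ``per_model`` is indexed by model id with columns M1_left, M1_right,
    SMA_left, SMA_right, average.  SDs use ddof=0 so single-model populations
    report SD = 0.
    """

    montage: MontageSpec
    per_model: pd.DataFrame
    incomplete: dict = field(default_factory=dict)  # model_id -> error message

    @property
    def population_mean(self) -> pd.Series:
        return self.per_model.mean()

    @property
    def population_sd(self) -> pd.Series:
        return self.per_model.std(ddof=0)

    @property
    def objective(self) -> float:
        """Population mean of the four-ROI average field strength (V/m)."""
        return float(self.per_model["average"].mean())


@dataclass(frozen=True)
class SensitivityScenario:
    """Named per-tissue conductivity multipliers (1.0 elsewhere)."""

    name: str
    multipliers: tuple  # of (tissue_name, factor)

    def apply(self, table: TissueConductivityTable) -> TissueConductivityTable:
        for _, f in self.multipliers:
            if f <= 0:
                raise ValueError(f"scenario {self.name!r}: non-positive multiplier {f}")
        return table.scaled(dict(self.multipliers))


def default_scenarios() -> list:
    """Baseline plus one-at-a-time bone ±50% (compact and spongy jointly) and
    CSF ±10% perturbations."""
    bone = lambda f: (("compact_bone", f), ("spongy_bone", f))
    return [
        SensitivityScenario("baseline", ()),
        SensitivityScenario("bone_x0.5", bone(0.5)),
        SensitivityScenario("bone_x1.5", bone(1.5)),
        SensitivityScenario("csf_x0.9", (("CSF", 0.9),)),
        SensitivityScenario("csf_x1.1", (("CSF", 1.1),)),
    ]


def _solve_roi_means(
    model: VoxelModel,
    montage: MontageSpec,
    table: TissueConductivityTable,
    rois,
    settings: SolverSettings,
) -> dict:
    placement = place_electrodes(model, montage, settings.electrode)
    source = build_source(placement.model, placement, montage.current_mA)
    phi = solve_potential(placement.model, table, source, settings.tol, settings.maxiter)
    ef = compute_efield(phi, placement.model)
    return roi_means_for_model(
        ef, placement.model, rois, settings.sampling_depth_mm, settings.n_surface_points
    )


def evaluate_montage(
    models,
    montage: MontageSpec,
    rois=None,
    settings: SolverSettings | None = None,
    table: TissueConductivityTable | None = None,
    cache: dict | None = None,
) -> MontageEvaluation:
    """Run place -> solve -> surface-map -> ROI-mean on every model and
    aggregate across the population.

    ``cache`` (optional dict) memoizes per-model ROI means keyed by
    (model id, montage, conductivity signature, h) so sensitivity scenarios
    re-solve only what changed.  A failing model is recorded in
    ``incomplete`` and excluded from the aggregate.
    """
    if len(models) == 0:
        raise ValueError("at least one model required")
    rois = default_rois() if rois is None else rois
    settings = settings or SolverSettings()
    table = table or conductivity_table()
    rows, index, incomplete = [], [], {}
    settings_key = (
        settings.tol,
        settings.n_surface_points,
        settings.sampling_depth_mm,
        settings.electrode,
        tuple(sorted(r.name for r in rois)),
    )
    for model in models:
        key = (
            model.fingerprint(),
            montage.name,
            montage.current_mA,
            table.signature(),
            settings_key,
        )
        if cache is not None and key in cache:
            means = cache[key]
        else:
            try:
                means = _solve_roi_means(model, montage, table, rois, settings)
            except Exception as exc:  # noqa: BLE001 - recorded per spec contract
                log.error("montage %s failed on %s: %s", montage.name, model.model_id, exc)
                incomplete[model.model_id] = str(exc)
                continue
            if cache is not None:
                cache[key] = means
        row = [means[name] for name in ROI_ORDER]
        rows.append(row + [float(np.mean(row))])
        index.append(model.model_id)
    per_model = pd.DataFrame(rows, index=index, columns=list(ROI_ORDER) + ["average"])
    return MontageEvaluation(montage, per_model, incomplete)


def rank_montages(evaluations) -> pd.DataFrame:
    """Descending table of population mean ± SD per ROI and of the four-ROI
    average; ties on the objective keep candidate-list order and are flagged."""
    if not evaluations:
        raise ValueError("no evaluations to rank")
    ids0 = tuple(evaluations[0].per_model.index)
    rows = []
    for ev in evaluations:
        if tuple(ev.per_model.index) != ids0:
            raise ValueError("evaluations span different model populations")
        if ev.incomplete:
            raise ValueError(f"montage {ev.montage.name} is incomplete on {sorted(ev.incomplete)}")
        mean, sd = ev.population_mean, ev.population_sd
        row = {"montage": ev.montage.name}
        for roi in ROI_ORDER:
            row[f"{roi}_mean"] = mean[roi]
            row[f"{roi}_sd"] = sd[roi]
        row["average_mean"] = mean["average"]
        row["average_sd"] = sd["average"]
        rows.append(row)
    df = pd.DataFrame(rows)
    order = np.argsort(-df["average_mean"].to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    obj = df["average_mean"].to_numpy()
    df["tied"] = np.isin(obj, obj[np.nonzero(np.diff(obj) == 0)[0]]) if len(obj) > 1 else False
    return df


def per_model_optima(evaluations) -> pd.Series:
    """For each model, the montage with the largest four-ROI average; returns
    montage -> model count (counts sum to the population size).  Per-model
    ties go to the earlier montage in candidate order and are logged."""
    if not evaluations:
        raise ValueError("no evaluations")
    avg = pd.DataFrame(
        {ev.montage.name: ev.per_model["average"] for ev in evaluations}
    )
    names = list(avg.columns)
    arr = avg.to_numpy()
    best = arr.argmax(axis=1)  # first max wins = candidate-list order
    ties = (arr == arr.max(axis=1, keepdims=True)).sum(axis=1) > 1
    for mid in avg.index[ties]:
        log.warning("model %s: tied optimum, assigned to candidate-order winner", mid)
    counts = pd.Series(0, index=names, dtype=int)
    for bi in best:
        counts.iloc[bi] += 1
    return counts


def sensitivity_analysis(
    models,
    montages,
    scenarios=None,
    rois=None,
    settings: SolverSettings | None = None,
    base_table: TissueConductivityTable | None = None,
    cache: dict | None = None,
) -> dict:
    """Re-run the full montage evaluation under each conductivity scenario.

    Returns ``{"tables": {scenario: ranked DataFrame}, "optimal": {scenario:
    montage name}, "robust_optimal_set": sorted set of scenario winners}``.
    """
    scenarios = default_scenarios() if scenarios is None else scenarios
    base = base_table or conductivity_table()
    cache = {} if cache is None else cache
    tables, optimal = {}, {}
    for scen in scenarios:
        table = scen.apply(base)
        evals = [
            evaluate_montage(models, m, rois, settings, table, cache) for m in montages
        ]
        ranked = rank_montages(evals)
        tables[scen.name] = ranked
        optimal[scen.name] = str(ranked.iloc[0]["montage"])
    return {
        "tables": tables,
        "optimal": optimal,
        "robust_optimal_set": sorted(set(optimal.values())),
    }


def montage_table_csv(ranked: pd.DataFrame, path) -> None:
    """Write the ranked montage table with 6-significant-digit formatting
    (bit-stable across reruns for a fixed seed/config)."""
    ranked.to_csv(path, index=False, float_format="%.6g")
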