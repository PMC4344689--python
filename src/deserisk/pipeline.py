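"""End-to-end orchestration: simulate -> weigh -> evaluate -> zone -> validate.

The run is fully deterministic given one seed: sub-seeds for the indicator
fields, the region partition, the loss noise and the entropy subsample are
derived from it. A JSON manifest records the seed, a hash of the indicator
configuration, package versions and any warnings.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fuzzy, membership, synthetic, validation, weighting
from .config import FACTORS, IndicatorConfigTable, canonical_config
from .errors import ValidationError
from .grid import GridLayer, write_ascii_grid

WEIGHT_MODES = ("table", "entropy", "combined")


@dataclass
class PipelineResult:
    """Everything one run produces, kept in memory; write_outputs saves it."""

    config: IndicatorConfigTable
    model: fuzzy.RiskModel
    weights: dict  # factor -> WeightVector
    indicator_layers: list
    regions: GridLayer
    factor_indices: dict  # factor -> GridLayer
    ddri: GridLayer
    grades: GridLayer
    zones: pd.DataFrame
    losses: GridLayer
    report: validation.ValidationReport
    manifest: dict = field(default_factory=dict)


def _config_hash(config: IndicatorConfigTable) -> str:
    text = config.to_frame().to_csv(index=False)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def factor_weight_vectors(
    config: IndicatorConfigTable,
    mode: str = "table",
    layers: list[GridLayer] | None = None,
    seed: int = 0,
) -> dict:
    """Per-factor indicator weight vectors (renormalized within each factor).

    mode 'table' uses the configured combined weights; 'entropy' derives
    objective weights from the layers' cell values; 'combined' multiplies
    the configured weights (as the subjective side) with entropy weights.
    """
    if mode not in WEIGHT_MODES:
        raise ValidationError(f"unknown weight mode {mode!r}")
    if mode in ("entropy", "combined"):
        if layers is None:
            raise ValidationError(f"mode {mode!r} needs indicator layers")
        from .indicators import minmax_normalize

        by_name = {l.name: l for l in layers}
        normalized = []
        for spec in config:
            direction = "benefit" if spec.membership_direction == "increasing" else "cost"
            normalized.append(minmax_normalize(by_name[spec.name], direction))
        matrix, names = weighting.decision_matrix_from_layers(normalized, seed=seed)
        objective = weighting.entropy_weights(matrix, names)
    out = {}
    for factor in FACTORS:
        specs = config.by_factor(factor)
        names = [s.name for s in specs]
        if mode == "table":
            raw = np.array([s.weight for s in specs], dtype=float)
        elif mode == "entropy":
            raw = np.array([objective[n] for n in names])
        else:
            subj = np.array([s.weight for s in specs], dtype=float)
            raw = subj * np.array([objective[n] for n in names])
        out[factor] = weighting.WeightVector.from_raw(names, raw)
    return out


def evaluate_factors(
    config: IndicatorConfigTable,
    layers: list[GridLayer],
    weights: dict,
    model: fuzzy.RiskModel,
) -> tuple[dict, dict]:
    """Fuzzy-evaluate each factor; returns (factor B-vectors, factor index layers)."""
    by_name = {l.name: l for l in layers}
    factor_b, factor_idx = {}, {}
    for factor in FACTORS:
        specs = config.by_factor(factor)
        results = [membership.grade_layers(by_name[s.name], s) for s in specs]
        b = fuzzy.factor_evaluate(results, weights[factor])
        b.name = factor
        factor_b[factor] = b
        factor_idx[factor] = fuzzy.defuzzify(b, model.grade_scores)
    return factor_b, factor_idx


def run_pipeline(
    synth: synthetic.SyntheticConfig | None = None,
    seed: int | None = None,
    weight_mode: str = "table",
    model: fuzzy.RiskModel | None = None,
) -> PipelineResult:
    """Full synthetic run: simulate, weigh, evaluate, grade, zone, validate."""
    synth = synth or synthetic.SyntheticConfig()
    if seed is not None:
        synth = synthetic.SyntheticConfig(
            shape=synth.shape,
            cell_size=synth.cell_size,
            indicators=synth.indicators,
            smoothing_cells=synth.smoothing_cells,
            n_regions=synth.n_regions,
            loss_slope=synth.loss_slope,
            loss_noise_sd=synth.loss_noise_sd,
            seed=seed,
        )
    config = synth.indicators
    model = model or fuzzy.RiskModel.from_config(config)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        layers = synthetic.generate_indicator_layers(synth)
        regions = synthetic.generate_regions(
            synth.shape, synth.n_regions, seed=synth.seed + 1, cell_size=synth.cell_size
        )
        weights = factor_weight_vectors(
            config, mode=weight_mode, layers=layers, seed=synth.seed + 3
        )
        _, factor_idx = evaluate_factors(config, layers, weights, model)
        risk = fuzzy.ddri(
            factor_idx["hazard"],
            factor_idx["exposure"],
            factor_idx["vulnerability"],
            factor_idx["restorability"],
            model,
        )
        grades = fuzzy.grade_risk(risk, model)
        losses = synthetic.generate_biomass_losses(
            risk, synth.loss_slope, synth.loss_noise_sd, seed=synth.seed + 2
        )
        zones = fuzzy.zonal_stats(grades, risk, regions)
        pairs = validation.regional_pairs(risk, losses, regions)
        report = validation.fit_linear(pairs)

    manifest = {
        "seed": synth.seed,
        "grid_shape": list(synth.shape),
        "cell_size_km": synth.cell_size,
        "n_regions": synth.n_regions,
        "weight_mode": weight_mode,
        "config_hash": _config_hash(config),
        "loss_slope": synth.loss_slope,
        "loss_noise_sd": synth.loss_noise_sd,
        "versions": _versions(),
        "warnings": [str(w.message) for w in caught],
        "r_squared": report.r_squared,
        "fitted_slope": report.slope,
    }
    return PipelineResult(
        config=config, model=model, weights=weights, indicator_layers=layers,
        regions=regions, factor_indices=factor_idx, ddri=risk, grades=grades,
        zones=zones, losses=losses, report=report, manifest=manifest,
    )


def _versions() -> dict:
    import numpy
    import pandas
    import scipy

    from . import __version__

    return {
        "deserisk": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }


def write_outputs(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write rasters (ESRI ASCII), tables (CSV) and the JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for layer in result.indicator_layers:
        write_ascii_grid(layer, out / f"indicator_{layer.name}.asc")
    write_ascii_grid(result.regions, out / "regions.asc")
    for factor, layer in result.factor_indices.items():
        write_ascii_grid(layer, out / f"factor_{factor}.asc")
    write_ascii_grid(result.ddri, out / "ddri.asc")
    write_ascii_grid(result.grades, out / "risk_grade.asc")
    write_ascii_grid(result.losses, out / "biomass_loss.asc")
    result.zones.to_csv(out / "zonal_stats.csv")
    result.report.pairs.to_csv(out / "regional_pairs.csv", index=False)
    weight_rows = []
    for factor, wv in result.weights.items():
        for name, w in zip(wv.names, wv.w):
            weight_rows.append({"factor": factor, "indicator": name, "weight": w})
    pd.DataFrame(weight_rows).to_csv(out / "weights.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    return out
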