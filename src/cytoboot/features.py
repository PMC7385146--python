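"""Population-level immune feature derivation.

Three feature families are computed from labeled single-cell data:

* **frequencies** — a population's share of a sample, in percent. Mononuclear
  (non-neutrophil) populations are expressed as a percentage of the sample's
  non-neutrophil cells and sum to 100 per sample; the neutrophil population is
  expressed as a percentage of all cells.
* **basal signaling** — per (sample, population, functional marker) the median
  arcsinh-scale intensity over the population's cells.
* **signaling responses** — the *difference* of a post-baseline sample's
  median from the same patient's baseline median, per population and marker
  ("arcsinh ratio" in the cytometry literature: a difference on the arcsinh
  scale, never a quotient).

Empty populations yield missing values, never zeros.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import ARCSINH, RAW, CellTable, Study
from .errors import ParameterError, StateError

log = logging.getLogger(__name__)

DEFAULT_COFACTOR = 5.0

MONONUCLEAR = "mononuclear"
ALL_LIVE = "all_live"


def arcsinh(values, cofactor: float = DEFAULT_COFACTOR):
    """Elementwise ``asinh(x / cofactor)`` — the cytometry variance-stabilizer."""
    if cofactor <= 0:
        raise ParameterError(f"cofactor must be > 0, got {cofactor}")
    return np.arcsinh(np.asarray(values, dtype=float) / cofactor)


def inverse_arcsinh(values, cofactor: float = DEFAULT_COFACTOR):
    """Inverse transform: ``cofactor * sinh(x)``."""
    if cofactor <= 0:
        raise ParameterError(f"cofactor must be > 0, got {cofactor}")
    return cofactor * np.sinh(np.asarray(values, dtype=float))


def arcsinh_transform(table: CellTable, cofactor: float = DEFAULT_COFACTOR) -> CellTable:
    """Return a new arcsinh-scale :class:`CellTable`; refuses to transform twice."""
    if table.scale == ARCSINH:
        raise StateError(
            f"sample {table.sample_id!r} is already arcsinh-scaled; "
            "double transformation would silently corrupt intensities"
        )
    assert table.scale == RAW
    data = pd.DataFrame(
        arcsinh(table.data.to_numpy(), cofactor), columns=table.data.columns
    )
    return CellTable(table.sample_id, data, table.panel, labels=table.labels, scale=ARCSINH)


def _require_labels(study: Study) -> None:
    missing = [sid for sid in study.sample_ids if study.samples[sid].labels is None]
    if missing:
        raise StateError(f"samples without population labels: {missing}")


def population_frequencies(study: Study, denominator: str = MONONUCLEAR) -> pd.DataFrame:
    """Long-format population frequencies: sample_id, population, value (%).

    With ``denominator='mononuclear'`` (the default), non-neutrophil
    populations are percentages of non-neutrophil cells (summing to 100 per
    sample) while neutrophils are percentages of all cells. With
    ``denominator='all_live'`` every population is a percentage of all cells.
    """
    if denominator not in (MONONUCLEAR, ALL_LIVE):
        raise ParameterError(f"unknown denominator {denominator!r}")
    _require_labels(study)
    neutro = study.neutrophil_populations()
    populations = sorted(
        set(study.population_compartments)
        | {p for sid in study.sample_ids for p in study.samples[sid].labels.unique()}
    )
    rows = []
    for sid in study.sample_ids:
        labels = study.samples[sid].labels
        counts = labels.value_counts()
        n_total = len(labels)
        n_mono = n_total - int(sum(counts.get(p, 0) for p in neutro))
        for pop in populations:
            c = int(counts.get(pop, 0))
            if denominator == ALL_LIVE or pop in neutro:
                value = 100.0 * c / n_total
            else:
                value = 100.0 * c / n_mono if n_mono else np.nan
            rows.append((sid, pop, value))
    return pd.DataFrame(rows, columns=["sample_id", "population", "value"])


def population_signaling(study: Study) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Basal medians and baseline-subtracted responses per population.

    Returns ``(basal, response)``; both are long-format frames with columns
    sample_id, population, marker, value. ``basal`` covers every sample;
    ``response`` covers post-baseline samples of patients that have a baseline
    sample (others are omitted with a logged warning). Populations empty in a
    given sample produce NaN values.
    """
    _require_labels(study)
    for sid in study.sample_ids:
        if study.samples[sid].scale != ARCSINH:
            raise StateError(f"sample {sid!r} is not arcsinh-scaled")
    func = list(study.panel.functional)
    populations = sorted(
        set(study.population_compartments)
        | {p for sid in study.sample_ids for p in study.samples[sid].labels.unique()}
    )

    # per-sample medians, as {sid: DataFrame population x marker}
    medians: dict[str, pd.DataFrame] = {}
    for sid in study.sample_ids:
        ct = study.samples[sid]
        med = (
            ct.data[func]
            .groupby(ct.labels.to_numpy())
            .median()
            .reindex(populations)
        )
        medians[sid] = med

    basal_rows = []
    for sid in study.sample_ids:
        for pop in populations:
            for marker in func:
                basal_rows.append((sid, pop, marker, medians[sid].loc[pop, marker]))
    basal = pd.DataFrame(basal_rows, columns=["sample_id", "population", "marker", "value"])

    response_rows = []
    baseline_tp = study.baseline_timepoint
    skipped = set()
    for sid in study.sample_ids:
        md = study.metadata.loc[sid]
        if md["timepoint"] == baseline_tp:
            continue
        base_sid = study.baseline_sample_of(md["patient_id"])
        if base_sid is None:
            skipped.add(md["patient_id"])
            continue
        diff = medians[sid] - medians[base_sid]
        for pop in populations:
            for marker in func:
                response_rows.append((sid, pop, marker, diff.loc[pop, marker]))
    if skipped:
        log.warning(
            "no baseline sample for patient(s) %s; their responses are omitted",
            sorted(skipped),
        )
    response = pd.DataFrame(
        response_rows, columns=["sample_id", "population", "marker", "value"]
    )
    return basal, response


def export_features(
    frequencies: pd.DataFrame,
    basal: pd.DataFrame,
    response: pd.DataFrame,
    path,
) -> None:
    """Tidy long-format export: sample_id, unit_id, feature_type, marker, value."""
    freq = frequencies.rename(columns={"population": "unit_id"}).assign(
        feature_type="frequency", marker=""
    )
    bas = basal.rename(columns={"population": "unit_id"}).assign(feature_type="basal")
    resp = response.rename(columns={"population": "unit_id"}).assign(
        feature_type="response"
    )
    cols = ["sample_id", "unit_id", "feature_type", "marker", "value"]
    pd.concat([freq[cols], bas[cols], resp[cols]], ignore_index=True).to_csv(
        path, index=False
    )
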