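"""Pearson functional connectivity, Fisher z-transform, and vectorization.

A subject's FC matrix is the Pearson correlation of every ROI-pair of its
time-series columns. Correlations are variance-stabilized with Fisher's
z = atanh(r) before any group-level modelling; unit correlations (possible in
toy data, not off-diagonal in real data) are clipped to ``1 - clip_eps`` to
keep z finite.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    FCFeatureTable,
    FCMatrix,
    PhenotypeTable,
    ROITimeSeries,
    upper_triangle_pairs,
)

DEFAULT_CLIP_EPS = 1e-7


def compute_fc(ts: ROITimeSeries) -> FCMatrix:
    """Pearson correlation of every column pair; symmetric with unit diagonal."""
    values = ts.values
    if values.shape[0] < 3:
        raise ValueError(
            f"subject {ts.subject_id!r}: {values.shape[0]} timepoints; "
            "Pearson correlation needs at least 3"
        )
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        region = int(np.argmax(sd == 0))
        label = ts.region_labels[region] if ts.region_labels else str(region)
        raise ValueError(
            f"subject {ts.subject_id!r}: region {label} has zero variance; "
            "correlation undefined"
        )
    r = np.corrcoef(values, rowvar=False)
    # guard against floating-point spill outside [-1, 1]
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return FCMatrix(ts.subject_id, r)


def fisher_z(r, clip_eps: float = DEFAULT_CLIP_EPS):
    """Fisher z-transform atanh(r) with |r| clipped to 1 - clip_eps.

    Accepts scalars or arrays; strictly increasing and odd in r.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    if not 0 < clip_eps < 1:
        raise ValueError("clip_eps must be in (0, 1)")
    z = np.arctanh(np.clip(r, -1.0 + clip_eps, 1.0 - clip_eps))
    return float(z) if z.ndim == 0 else z


def vectorize(fc: FCMatrix) -> np.ndarray:
    """Upper-triangle entries in canonical row-major order (length R(R-1)/2)."""
    return fc.values[np.triu_indices(fc.n_regions, k=1)]


def devectorize(row: np.ndarray, n_regions: int, subject_id: str = "") -> FCMatrix:
    """Inverse of :func:`vectorize`: rebuild the symmetric matrix, unit diagonal."""
    row = np.asarray(row, dtype=float)
    m = np.eye(n_regions)
    iu = np.triu_indices(n_regions, k=1)
    if row.shape != iu[0].shape:
        raise ValueError(f"expected {len(iu[0])} features for R={n_regions}, got {row.shape}")
    m[iu] = row
    m[(iu[1], iu[0])] = row
    return FCMatrix(subject_id, m)


def fc_feature_table(
    timeseries: list[ROITimeSeries],
    phenotypes: PhenotypeTable | None = None,
    clip_eps: float = DEFAULT_CLIP_EPS,
) -> FCFeatureTable:
    """Compute per-subject FC, Fisher z-transform, and stack into a feature table.

    Subject order follows ``phenotypes`` when given (every phenotype subject
    must have a time series); otherwise the input list order is used.
    """
    by_id = {ts.subject_id: ts for ts in timeseries}
    if len(by_id) != len(timeseries):
        raise ValueError("duplicate subject_id among time series")
    if phenotypes is not None:
        missing = [sid for sid in phenotypes.subject_ids if sid not in by_id]
        if missing:
            raise ValueError(f"subjects in phenotypes with no time series: {missing}")
        ordered = [by_id[sid] for sid in phenotypes.subject_ids]
    else:
        ordered = timeseries
    n_regions = ordered[0].n_regions
    for ts in ordered:
        if ts.n_regions != n_regions:
            raise ValueError(
                f"subject {ts.subject_id!r} has {ts.n_regions} regions, expected {n_regions}"
            )
    rows = [fisher_z(vectorize(compute_fc(ts)), clip_eps) for ts in ordered]
    return FCFeatureTable(
        [ts.subject_id for ts in ordered],
        upper_triangle_pairs(n_regions),
        np.vstack(rows),
        provenance=["fisher_z"],
    )
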