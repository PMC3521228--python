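"""Dataset filtering, log2 transformation and probe→gene collapsing.

Pipeline order is fixed: filter by array count, then log-transform, then
collapse probes.  Since log2 is monotone on positives, taking the per-sample
maximum before or after the transform is equivalent for positive data; the
fixed order makes the v <= 0 edge case (zeroed by the transform) behave
deterministically.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, LINEAR, LOG2
from .errors import ScaleError

logger = logging.getLogger(__name__)

#: default minimum array count: strictly more than six arrays
MIN_ARRAYS_DEFAULT = 7


def filter_datasets(datasets: list[ExpressionDataset],
                    min_arrays: int = MIN_ARRAYS_DEFAULT) -> list[ExpressionDataset]:
    """Keep datasets with at least ``min_arrays`` samples, order preserved.

    Each exclusion is logged; an empty result logs a warning rather than
    raising.
    """
    if min_arrays < 1:
        raise ValueError(f"min_arrays must be >= 1, got {min_arrays}")
    kept = []
    for ds in datasets:
        if ds.n_samples >= min_arrays:
            kept.append(ds)
        else:
            logger.info("excluding dataset %s: %d arrays < min_arrays=%d",
                        ds.dataset_id, ds.n_samples, min_arrays)
    if not kept:
        logger.warning("no dataset has >= %d arrays; result is empty", min_arrays)
    return kept


def log_transform(dataset: ExpressionDataset) -> ExpressionDataset:
    """log2-transform positive values; values <= 0 become 0.

    Values in (0, 1) yield negative log2 values and are kept as computed.
    Applying the transform to an already log2-scaled dataset raises.
    """
    if dataset.scale != LINEAR:
        raise ScaleError(
            f"dataset {dataset.dataset_id!r} is already on the {dataset.scale} scale")
    arr = dataset.values.to_numpy(dtype=float)
    out = np.zeros_like(arr)
    positive = arr > 0
    out[positive] = np.log2(arr[positive])
    values = pd.DataFrame(out, index=dataset.values.index,
                          columns=dataset.values.columns)
    return dataset.with_values(values, LOG2)


def collapse_probes(dataset: ExpressionDataset, probe_map: pd.Series,
                    min_mapped_fraction: float = 0.0) -> ExpressionDataset:
    """Collapse probe rows to one row per gene by the per-sample maximum.

    For a gene with several probes, each gene × sample cell is the maximum of
    that gene's probe values in that sample (not the single probe with the
    highest average).  Probes absent from ``probe_map`` are dropped with a
    logged count; gene rows come out sorted by identifier.

    Parameters
    ----------
    probe_map :
        probe→gene Series (many probes to one gene).
    min_mapped_fraction :
        Minimum fraction of probe rows that must be mappable; below it the
        call raises.
    """
    rows = dataset.values.index
    mapped_mask = rows.isin(probe_map.index)
    n_unmapped = int((~mapped_mask).sum())
    if mapped_mask.sum() == 0:
        raise ValueError(
            f"dataset {dataset.dataset_id!r}: no probe identifier present in the probe map")
    frac = mapped_mask.sum() / len(rows)
    if frac < min_mapped_fraction:
        raise ValueError(
            f"dataset {dataset.dataset_id!r}: only {frac:.1%} of probes are mappable "
            f"(< required {min_mapped_fraction:.1%})")
    if n_unmapped:
        logger.info("dataset %s: dropped %d unmapped probes",
                    dataset.dataset_id, n_unmapped)
    values = dataset.values.loc[mapped_mask]
    genes = probe_map.reindex(values.index)
    collapsed = values.groupby(genes.to_numpy()).max().sort_index()
    collapsed.index.name = "gene"
    return dataset.with_values(collapsed, dataset.scale)


def preprocess_dataset(dataset: ExpressionDataset, probe_map: pd.Series | None,
                       collapse: bool = True) -> ExpressionDataset:
    """log-transform and (optionally) collapse a single linear-scale dataset."""
    out = log_transform(dataset)
    if collapse and probe_map is not None:
        out = collapse_probes(out, probe_map)
    return out
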