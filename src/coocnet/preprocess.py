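"""Count-table filtering, environment splitting and uniform-size trimming.

Filtering order is fixed: a minimum-total-reads filter on the full table,
then an environment split, then a per-environment relative-abundance /
prevalence filter.  Environments with fewer samples than the trim size are
excluded from trimmed-subnetwork inference rather than silently truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from coocnet.io_model import AbundanceTable


@dataclass
class FilterReport:
    n_esvs_in: int
    n_esvs_out: int
    n_removed_by_total_reads: int = 0
    n_removed_by_abundance: int = 0
    n_removed_by_prevalence: int = 0
    samples_per_environment: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        removed = (self.n_removed_by_total_reads + self.n_removed_by_abundance
                   + self.n_removed_by_prevalence)
        if self.n_esvs_out != self.n_esvs_in - removed:
            raise ValueError("filter report removal counts do not add up")


class EnvironmentTooSmall(ValueError):
    """Raised when an environment has fewer samples than the trim size."""

    def __init__(self, n_samples: int, n_required: int):
        self.n_samples = n_samples
        self.n_required = n_required
        super().__init__(
            f"environment has {n_samples} samples; {n_required} required for "
            "trimming - excluded from trimmed-subnetwork inference"
        )


def filter_min_total_reads(
    table: AbundanceTable, min_total: int = 25
) -> tuple[AbundanceTable, FilterReport]:
    """Keep ESVs whose total count over all samples is at least ``min_total``."""
    row_sums = table.counts.sum(axis=1)
    keep = [e for e, s in zip(table.esv_ids, row_sums) if s >= min_total]
    out = table.subset_esvs(keep)
    report = FilterReport(
        n_esvs_in=table.n_esvs,
        n_esvs_out=out.n_esvs,
        n_removed_by_total_reads=table.n_esvs - out.n_esvs,
    )
    return out, report


def filter_abundance_prevalence(
    table: AbundanceTable,
    min_rel_abund: float = 1e-5,
    min_prevalence: float = 0.10,
) -> tuple[AbundanceTable, FilterReport]:
    """Drop rare ESVs within one environment's table.

    An ESV is removed when its overall relative abundance (row sum divided by
    the grand total) is below ``min_rel_abund`` OR it is present (count > 0)
    in fewer than ``min_prevalence`` of the samples.  Equality at either
    threshold keeps the ESV.  Removals are attributed to the abundance
    criterion first, then prevalence.
    """
    grand_total = table.counts.sum()
    if grand_total == 0:
        raise ValueError("cannot compute relative abundance: grand total is 0")
    rel = table.counts.sum(axis=1) / grand_total
    prevalence = (table.counts > 0).mean(axis=1) if table.n_samples else np.zeros(table.n_esvs)
    fail_abund = rel < min_rel_abund
    fail_prev = prevalence < min_prevalence
    keep = [e for e, fa, fp in zip(table.esv_ids, fail_abund, fail_prev)
            if not (fa or fp)]
    out = table.subset_esvs(keep)
    n_abund = int(fail_abund.sum())
    n_prev = int((fail_prev & ~fail_abund).sum())
    report = FilterReport(
        n_esvs_in=table.n_esvs,
        n_esvs_out=out.n_esvs,
        n_removed_by_abundance=n_abund,
        n_removed_by_prevalence=n_prev,
    )
    return out, report


def split_by_environment(table: AbundanceTable) -> dict[str, AbundanceTable]:
    """Partition samples by environment label (ESV rows retained in every part)."""
    unlabeled = [s for s in table.sample_ids if s not in table.environment_of]
    if unlabeled:
        raise ValueError(f"samples without environment label: {unlabeled[:5]}")
    by_env: dict[str, list[str]] = {}
    for s in table.sample_ids:
        by_env.setdefault(table.environment_of[s], []).append(s)
    return {env: table.subset_samples(samples) for env, samples in by_env.items()}


def trim_dataset(
    table: AbundanceTable,
    n_esvs: int = 400,
    n_samples: int = 360,
    seed: int = 0,
) -> AbundanceTable:
    """Trim to the ``n_esvs`` top-abundant ESVs and a random ``n_samples`` subset.

    The ESV ranking is by row sum (descending), ties broken by lexicographic
    ESV id, and is independent of the seed; the sample subset is drawn
    uniformly without replacement with the given seed.  Raises
    :class:`EnvironmentTooSmall` when the table has fewer than ``n_samples``
    samples, signalling that this environment is excluded.
    """
    if table.n_samples < n_samples:
        raise EnvironmentTooSmall(table.n_samples, n_samples)
    row_sums = table.counts.sum(axis=1)
    ranked = sorted(zip(table.esv_ids, row_sums), key=lambda t: (-t[1], t[0]))
    top = {e for e, _ in ranked[:n_esvs]}
    keep_esvs = [e for e in table.esv_ids if e in top]  # preserve row order
    rng = np.random.default_rng(seed)
    chosen = rng.choice(table.n_samples, size=n_samples, replace=False)
    keep_samples = [table.sample_ids[j] for j in sorted(chosen)]
    return table.subset_esvs(keep_esvs).subset_samples(keep_samples)
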