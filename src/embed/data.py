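"""Count-tensor container for multi-subject longitudinal OTU tables.

The central object is :class:`CountTensor`: read counts ``n[o, s, t]`` for
``O`` OTUs observed in ``S`` subjects on a shared daily time grid of length
``T``, together with an observation mask (subjects rarely have samples on
every day) and per-sample totals ``N_s(t)``.

Time is kept on a dense integer-day grid spanning the union of observed
days, because the latent dynamics downstream assume unit time steps; days
with no sample for a subject are simply masked out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CountTensor", "filter_otu_table"]


@dataclass
class CountTensor:
    """Read counts on a dense (OTU, subject, day) grid.

    Parameters
    ----------
    counts : ndarray, shape (O, S, T)
        Non-negative read counts (or abundance weights in absolute mode).
        Entries at unobserved (s, t) are ignored.
    subject_ids : sequence of str
    time_stamps : ndarray of int, shape (T,)
        Strictly increasing collection days shared by all subjects.
    otu_ids : sequence of str
    observed_mask : ndarray of bool, shape (S, T), optional
        True where a sample exists. Default: all observed.
    totals : ndarray, shape (S, T), optional
        Per-sample totals N_s(t). Default: column sums of ``counts``.
        Supplying measured absolute abundances here switches the model
        into absolute-abundance mode; values may then be non-integer.
    taxonomy : sequence of str or None
        Optional semicolon-separated lineage per OTU.
    """

    counts: np.ndarray
    subject_ids: Sequence[str]
    time_stamps: np.ndarray
    otu_ids: Sequence[str]
    observed_mask: np.ndarray | None = None
    totals: np.ndarray | None = None
    taxonomy: Sequence[str] | None = None
    totals_supplied: bool = field(default=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must have shape (O, S, T)")
        O, S, T = self.counts.shape
        self.time_stamps = np.asarray(self.time_stamps, dtype=int)
        if len(self.subject_ids) != S or len(self.otu_ids) != O:
            raise ValueError("subject_ids/otu_ids lengths inconsistent with counts")
        if self.time_stamps.shape != (T,):
            raise ValueError("time_stamps length inconsistent with counts")
        if np.any(np.diff(self.time_stamps) <= 0):
            raise ValueError("time_stamps must be strictly increasing")
        if self.observed_mask is None:
            self.observed_mask = np.ones((S, T), dtype=bool)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.observed_mask.shape != (S, T):
            raise ValueError("observed_mask must have shape (S, T)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.totals is None:
            self.totals = self.counts.sum(axis=0)
            self.totals_supplied = False
        else:
            self.totals = np.asarray(self.totals, dtype=float)
            if self.totals.shape != (S, T):
                raise ValueError("totals must have shape (S, T)")
            self.totals_supplied = True
        if np.any(self.totals[self.observed_mask] <= 0):
            raise ValueError("every observed sample must have a positive total")

    # ------------------------------------------------------------------
    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[1]

    @property
    def n_times(self) -> int:
        return self.counts.shape[2]

    @property
    def n_samples(self) -> int:
        """Number of observed (subject, day) samples."""
        return int(self.observed_mask.sum())

    def relative_abundances(self) -> np.ndarray:
        """Compositions x[o, s, t] = n / sum_o n on observed samples.

        Always normalized over the counts themselves; externally supplied
        totals act as per-sample weights in the likelihood, not as the
        composition denominator.
        """
        x = np.zeros_like(self.counts)
        m = self.observed_mask
        colsum = self.counts.sum(axis=0)
        if np.any(colsum[m] <= 0):
            raise ValueError("observed samples must contain at least one read")
        with np.errstate(invalid="ignore", divide="ignore"):
            x[:, m] = self.counts[:, m] / colsum[m]
        return x

    def equal_depth(self, rtol: float = 1e-9) -> bool:
        """True when all observed totals coincide (relative-count regime)."""
        tot = self.totals[self.observed_mask]
        return bool(np.allclose(tot, tot[0], rtol=rtol))

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        sample_meta: pd.DataFrame | None = None,
        taxonomy_col: str = "taxonomy",
    ) -> "CountTensor":
        """Build a tensor from a wide OTU × sample DataFrame.

        Sample columns are labelled ``"subject:day"`` unless ``sample_meta``
        (indexed by sample name, columns ``subject`` and ``day``) is given.
        Days absent between a subject's first and last observation are
        masked as missing; a dense daily grid over the union of observed
        days is used.
        """
        table = table.copy()
        taxonomy = None
        if taxonomy_col in table.columns:
            taxonomy = table[taxonomy_col].astype(str).tolist()
            table = table.drop(columns=[taxonomy_col])

        if table.columns.duplicated().any():
            dups = table.columns[table.columns.duplicated()].tolist()
            raise ValueError(f"duplicated sample column(s): {dups}")

        if sample_meta is not None:
            pairs = [
                (str(sample_meta.loc[c, "subject"]), int(sample_meta.loc[c, "day"]))
                for c in table.columns
            ]
        else:
            pairs = []
            for c in table.columns:
                try:
                    subj, day = str(c).rsplit(":", 1)
                    pairs.append((subj, int(day)))
                except ValueError as exc:
                    raise ValueError(
                        f"sample column {c!r} does not follow 'subject:day'"
                    ) from exc
        seen: set[tuple[str, int]] = set()
        for p in pairs:
            if p in seen:
                raise ValueError(f"duplicate (subject, day) sample: {p}")
            seen.add(p)

        values = table.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = [
                (table.index[i], table.columns[j])
                for i, j in zip(*np.where(pd.DataFrame(table).map(
                    lambda v: not isinstance(v, (int, float, np.integer, np.floating))
                ).to_numpy()))
            ]
            raise ValueError(f"non-numeric count cell(s): {bad[:5]}")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at OTU {table.index[i]!r}, sample {table.columns[j]!r}"
            )

        subjects = sorted({s for s, _ in pairs})
        days = np.arange(min(d for _, d in pairs), max(d for _, d in pairs) + 1)
        day_index = {int(d): i for i, d in enumerate(days)}
        O, S, T = len(table.index), len(subjects), len(days)
        counts = np.zeros((O, S, T))
        mask = np.zeros((S, T), dtype=bool)
        s_index = {s: i for i, s in enumerate(subjects)}
        for col, (subj, day) in zip(table.columns, pairs):
            s, t = s_index[subj], day_index[day]
            counts[:, s, t] = table[col].to_numpy()
            mask[s, t] = True
        return cls(
            counts=counts,
            subject_ids=subjects,
            time_stamps=days,
            otu_ids=[str(i) for i in table.index],
            observed_mask=mask,
            taxonomy=taxonomy,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Inverse of :meth:`from_dataframe` (observed samples only)."""
        cols: dict[str, np.ndarray] = {}
        for s, subj in enumerate(self.subject_ids):
            for t, day in enumerate(self.time_stamps):
                if self.observed_mask[s, t]:
                    cols[f"{subj}:{day}"] = self.counts[:, s, t]
        df = pd.DataFrame(cols, index=list(self.otu_ids))
        if self.taxonomy is not None:
            df["taxonomy"] = list(self.taxonomy)
        return df


def filter_otu_table(
    data: CountTensor,
    min_mean_abundance: float = 0.0,
    min_prevalence: float = 0.0,
) -> CountTensor:
    """Drop rare OTUs by mean relative abundance and prevalence.

    An OTU is kept when its mean relative abundance over observed samples
    is >= ``min_mean_abundance`` and it is nonzero in at least
    ``min_prevalence`` (a fraction) of observed samples. Surviving counts
    are left untouched; per-sample totals are recomputed from them unless
    they were externally supplied.
    """
    if not (0 <= min_mean_abundance <= 1 and 0 <= min_prevalence <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    x = data.relative_abundances()[:, data.observed_mask]  # (O, n_samples)
    keep = (x.mean(axis=1) >= min_mean_abundance) & (
        (x > 0).mean(axis=1) >= min_prevalence
    )
    if not keep.any():
        raise ValueError("filter would remove every OTU")
    return CountTensor(
        counts=data.counts[keep],
        subject_ids=list(data.subject_ids),
        time_stamps=data.time_stamps,
        otu_ids=[o for o, k in zip(data.otu_ids, keep) if k],
        observed_mask=data.observed_mask,
        totals=data.totals if data.totals_supplied else None,
        taxonomy=(
            [tx for tx, k in zip(data.taxonomy, keep) if k]
            if data.taxonomy is not None
            else None
        ),
    )
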