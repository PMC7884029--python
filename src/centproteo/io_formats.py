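"""Reading, validating and writing the study's file formats.

All tabular inputs and outputs are plain TSV with a header row; gene
sets travel as GMT (set name, description, then tab-separated symbols).
A :class:`Study` bundles the three validated input tables with sample
and aptamer order canonicalized (sorted by identifier) so every
downstream computation is order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("centproteo")

VALID_GROUPS = {"centenarian", "offspring", "control"}

__all__ = ["Study", "StudyValidationError", "load_study", "write_study",
           "read_gene_sets", "write_gene_sets", "write_results"]


class StudyValidationError(ValueError):
    """Input tables are inconsistent; the message names offending records."""


@dataclass
class Study:
    """Validated expression matrix + sample annotations + aptamer annotations."""

    expression: pd.DataFrame  # samples x aptamers, strictly positive RFU
    samples: pd.DataFrame     # indexed by sample_id
    aptamers: pd.DataFrame    # indexed by aptamer_id

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_aptamers(self) -> int:
        return self.expression.shape[1]

    def log_rfu(self) -> pd.DataFrame:
        """Natural-log transformed expression."""
        return np.log(self.expression)


def validate_study(expression: pd.DataFrame, samples: pd.DataFrame,
                   aptamers: pd.DataFrame) -> Study:
    """Cross-check the three tables and return a canonically ordered Study."""
    expr_samples = set(expression.index)
    tab_samples = set(samples.index)
    missing = sorted(expr_samples - tab_samples)
    if missing:
        raise StudyValidationError(
            f"samples in expression matrix but not in sample table: {missing[:10]}")
    extra = sorted(tab_samples - expr_samples)
    if extra:
        raise StudyValidationError(
            f"samples in sample table but not in expression matrix: {extra[:10]}")
    if samples.index.duplicated().any():
        dups = samples.index[samples.index.duplicated()].tolist()
        raise StudyValidationError(f"duplicate sample ids: {dups[:10]}")
    expr_apts = set(expression.columns)
    tab_apts = set(aptamers.index)
    if expr_apts != tab_apts:
        off = sorted(expr_apts.symmetric_difference(tab_apts))
        raise StudyValidationError(
            f"aptamer ids disagree between matrix and aptamer table: {off[:10]}")
    if aptamers.index.duplicated().any():
        dups = aptamers.index[aptamers.index.duplicated()].tolist()
        raise StudyValidationError(f"duplicate aptamer ids: {dups[:10]}")
    bad_groups = set(samples["group"]) - VALID_GROUPS
    if bad_groups:
        raise StudyValidationError(f"unknown group labels: {sorted(bad_groups)}")
    vals = expression.to_numpy()
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        rows, cols = np.where(~(np.isfinite(vals) & (vals > 0)))
        offenders = [(expression.index[r], expression.columns[c])
                     for r, c in zip(rows[:10], cols[:10])]
        raise StudyValidationError(
            f"non-positive or non-finite RFU values at (sample, aptamer): {offenders}")
    order_s = expression.index.sort_values()
    order_a = expression.columns.sort_values()
    return Study(expression.loc[order_s, order_a],
                 samples.loc[order_s],
                 aptamers.loc[order_a])


def load_study(expression_path, samples_path, aptamers_path) -> Study:
    """Read the TSV triplet and return a validated, canonically ordered Study."""
    expression = pd.read_csv(expression_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    aptamers = pd.read_csv(aptamers_path, sep="\t", index_col=0)
    return validate_study(expression, samples, aptamers)


def write_study(study: Study, expression_path, samples_path, aptamers_path) -> None:
    study.expression.to_csv(expression_path, sep="\t")
    study.samples.to_csv(samples_path, sep="\t")
    study.aptamers.to_csv(aptamers_path, sep="\t")


def read_gene_sets(gmt_path) -> dict[str, set]:
    """Parse a GMT file into {set name: unique symbol set}.

    Duplicate symbols within a line are deduplicated; empty sets are
    dropped with a warning.  Malformed lines (fewer than 3 fields)
    raise with the line number.
    """
    collection: dict[str, set] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{gmt_path}: malformed GMT line {lineno}: "
                    "expected >= 3 tab-separated fields")
            name, _desc, *symbols = fields
            members = {s for s in symbols if s}
            if not members:
                logger.warning("dropping empty gene set %r (line %d)", name, lineno)
                continue
            collection[name] = members
    return collection


def write_gene_sets(collection: dict[str, set], gmt_path,
                    description: str = "na") -> None:
    """Serialize {name: symbols} as GMT with sorted members (deterministic)."""
    with open(gmt_path, "w") as fh:
        for name in collection:
            fh.write("\t".join([name, description, *sorted(collection[name])]) + "\n")


def write_results(records: pd.DataFrame, path, sort_by: tuple = ("p", "aptamer_id")) -> None:
    """Write a results table deterministically.

    Columns keep their schema order; floats use 6 significant digits;
    rows sort by p-value then identifier (falling back to the existing
    order when those columns are absent).
    """
    df = records.copy()
    if df.index.name is not None:
        df = df.reset_index()
    by = [c for c in sort_by if c in df.columns]
    if by:
        df = df.sort_values(by, kind="mergesort")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
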