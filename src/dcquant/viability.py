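"""Progeny-survival bookkeeping and the contingency tests applied to it.

Viability assays score a brood as embryos laid, dead embryos, dead larvae,
and surviving adults.  Genotypes are compared by pooling dead embryos and
dead larvae into one "dead" category against surviving adults, with Fisher's
exact test for embryonic-exposure assays and a chi-square test for
larval-exposure on/off-auxin survivor counts.  Replicate counts are summed
before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ViabilityRecord:
    """One genotype/condition brood tally; laid = dead + dead + adults."""

    genotype: str
    condition: str
    laid: int
    dead_embryo: int
    dead_larva: int
    adult: int

    def __post_init__(self) -> None:
        for name in ("laid", "dead_embryo", "dead_larva", "adult"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.laid != self.dead_embryo + self.dead_larva + self.adult:
            raise ValueError(
                "count identity violated: laid must equal dead embryos + dead larvae + adults"
            )

    @property
    def dead(self) -> int:
        return self.dead_embryo + self.dead_larva


@dataclass
class ContingencyTable:
    """A 2x2 table of non-negative integer counts with axis labels."""

    cells: np.ndarray
    row_labels: tuple[str, str] = ("a", "b")
    col_labels: tuple[str, str] = ("x", "y")

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if np.any(self.cells < 0):
            raise ValueError("cells must be non-negative")
        if self.cells.sum() == 0:
            raise ValueError("table has zero total")


@dataclass
class BroodResult:
    """Embryonic viability (hatched/laid) and larval viability (adults/hatched).

    ``larval_viability`` is ``None`` when nothing hatched.
    """

    total_eggs: int
    embryonic_viability: float
    larval_viability: Optional[float]


def dead_live_table(record_a: ViabilityRecord, record_b: ViabilityRecord) -> ContingencyTable:
    """Rows = genotypes, columns = (dead = embryos + larvae, live = adults)."""
    cells = np.array(
        [[record_a.dead, record_a.adult], [record_b.dead, record_b.adult]], dtype=np.int64
    )
    return ContingencyTable(
        cells,
        row_labels=(record_a.genotype, record_b.genotype),
        col_labels=("dead", "live"),
    )


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact p (point-probability rule).

    Sums the hypergeometric probabilities of all tables with the observed
    margins that are no more probable than the observed table.  A table with
    a zero margin has a single admissible configuration, so p = 1.
    """
    _, p = stats.fisher_exact(table.cells, alternative="two-sided")
    return float(min(p, 1.0))


def chi_square(table: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction.

    The Yates-corrected variant is available behind ``yates=True``.
    Expected cells must all be positive.
    """
    expected = stats.contingency.expected_freq(table.cells)
    if np.any(expected <= 0):
        raise ValueError("chi-square requires all expected cells > 0")
    res = stats.chi2_contingency(table.cells, correction=yates)
    return float(res.statistic), float(res.pvalue)


def survival_ratio(on_auxin_survivors: int, off_auxin_survivors: int) -> float:
    """Survivors on auxin over survivors off auxin (may exceed 1 by sampling)."""
    if off_auxin_survivors <= 0:
        raise ValueError("off-auxin survivor count must be positive")
    if on_auxin_survivors < 0:
        raise ValueError("survivor counts must be non-negative")
    return on_auxin_survivors / off_auxin_survivors


def brood_metrics(eggs_laid_per_day: Sequence[int], hatched: int, adults: int) -> BroodResult:
    """Per-parent brood summary from daily egg counts.

    Embryonic viability = hatched / total embryos; larval viability =
    adults / hatched (undefined when hatched = 0).
    """
    total = int(sum(eggs_laid_per_day))
    if total < 0 or hatched < 0 or adults < 0:
        raise ValueError("counts must be non-negative")
    if hatched > total:
        raise ValueError("hatched cannot exceed eggs laid")
    if adults > hatched:
        raise ValueError("adults cannot exceed hatched embryos")
    emb = hatched / total if total > 0 else 0.0
    larv = adults / hatched if hatched > 0 else None
    return BroodResult(total_eggs=total, embryonic_viability=emb, larval_viability=larv)


def aggregate_broods(results: Sequence[BroodResult]) -> dict:
    """Mean per-parent viabilities (parents with no hatched larvae are skipped
    for the larval mean)."""
    if not results:
        raise ValueError("no brood results to aggregate")
    emb = float(np.mean([r.embryonic_viability for r in results]))
    larv_vals = [r.larval_viability for r in results if r.larval_viability is not None]
    larv = float(np.mean(larv_vals)) if larv_vals else None
    return {
        "mean_embryonic_viability": emb,
        "mean_larval_viability": larv,
        "mean_total_eggs": float(np.mean([r.total_eggs for r in results])),
        "n_parents": len(results),
    }


# ---------------------------------------------------------------------------
# tabular entry points

def records_from_frame(df: pd.DataFrame) -> list[ViabilityRecord]:
    """Build records from a table with columns
    genotype, condition, laid, dead_embryo, dead_larva, adult.
    Replicate rows of one genotype/condition are summed before testing."""
    needed = {"genotype", "condition", "laid", "dead_embryo", "dead_larva", "adult"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"viability table is missing columns {sorted(missing)}")
    pooled = df.groupby(["genotype", "condition"], sort=False, as_index=False)[
        ["laid", "dead_embryo", "dead_larva", "adult"]
    ].sum()
    return [
        ViabilityRecord(
            genotype=row.genotype,
            condition=row.condition,
            laid=int(row.laid),
            dead_embryo=int(row.dead_embryo),
            dead_larva=int(row.dead_larva),
            adult=int(row.adult),
        )
        for row in pooled.itertuples()
    ]


def viability_tests(df: pd.DataFrame, reference: str, condition: str | None = None) -> pd.DataFrame:
    """Fisher's exact dead/live comparison of each genotype to a reference.

    Returns a tidy frame with one row per non-reference genotype.
    """
    records = records_from_frame(df)
    if condition is not None:
        records = [r for r in records if r.condition == condition]
    refs = [r for r in records if r.genotype == reference]
    if not refs:
        raise ValueError(f"reference genotype {reference!r} not found")
    ref = refs[0]
    rows = []
    for rec in records:
        if rec.genotype == reference:
            continue
        table = dead_live_table(rec, ref)
        rows.append(
            {
                "genotype": rec.genotype,
                "condition": rec.condition,
                "reference": reference,
                "test": "fisher_exact",
                "dead": rec.dead,
                "live": rec.adult,
                "ref_dead": ref.dead,
                "ref_live": ref.adult,
                "p_value": fisher_exact(table),
            }
        )
    return pd.DataFrame(rows)
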