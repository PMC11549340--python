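"""Closed-form assay quantifications.

Small, exactly specified arithmetic used throughout the study's
molecular assays:

- Livak 2^-ddCt relative expression (reference gene, default actb);
- ChIP/3C percent-input with the log2 dilution correction;
- protease-cleavage efficacy from a luciferase-release split;
- Pearson chi-square test of genotype segregation against a Mendelian
  ratio (1:2:1 for a heterozygote in-cross);
- rounded fraction-as-percent bookkeeping (e.g. 86/90 -> 96%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import pandas as pd
from scipy import stats

CT_COLUMNS = ("sample", "condition", "gene", "ct", "replicate")


@dataclass
class CtTable:
    """qPCR cycle-threshold measurements in long format."""

    frame: pd.DataFrame
    reference_gene: str = "actb"

    @classmethod
    def from_csv(cls, path: str, reference_gene: str = "actb") -> "CtTable":
        frame = pd.read_csv(path)
        missing = set(CT_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if (frame["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        return cls(frame=frame, reference_gene=reference_gene)

    def mean_ct(self, condition: str, gene: str) -> float:
        sel = self.frame[
            (self.frame["condition"] == condition) & (self.frame["gene"] == gene)
        ]
        if sel.empty:
            raise KeyError(f"no Ct rows for condition={condition!r} gene={gene!r}")
        return float(sel["ct"].mean())

    def fold_change(self, target_gene: str, test: str, control: str) -> float:
        """Replicate-mean Livak fold change of ``target_gene`` in ``test``
        relative to ``control``, normalized to the reference gene."""
        return ddct_fold_change(
            self.mean_ct(test, target_gene),
            self.mean_ct(test, self.reference_gene),
            self.mean_ct(control, target_gene),
            self.mean_ct(control, self.reference_gene),
        )


@dataclass(frozen=True)
class GenotypeCounts:
    n_wt: int
    n_het: int
    n_hom: int

    def __post_init__(self):
        if min(self.n_wt, self.n_het, self.n_hom) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_wt + self.n_het + self.n_hom == 0:
            raise ValueError("total count must be positive")

    def as_tuple(self):
        return (self.n_wt, self.n_het, self.n_hom)


def ddct_fold_change(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Livak relative quantification: 2^-ddCt.

    ddCt = (Ct_target - Ct_ref)_test - (Ct_target - Ct_ref)_control.
    Equal normalized Cts give fold 1; ddCt = -3 gives fold 8.
    """
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """ChIP-qPCR enrichment as percent of input chromatin.

    The input Ct is first adjusted for its dilution (log2(1/fraction)
    cycles), then compared with the IP Ct:
    100 * 2^((Ct_input - log2(1/fraction)) - Ct_IP).
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must be in (0, 1]")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def cleavage_efficacy(luc_free: float, luc_fusion: float) -> float:
    """Percent receptor cleavage from released vs fusion-retained
    luciferase intensity: 100 * free / (free + fusion)."""
    if luc_free < 0 or luc_fusion < 0:
        raise ValueError("intensities must be non-negative")
    total = luc_free + luc_fusion
    if total == 0:
        raise ZeroDivisionError("both luciferase intensities are zero")
    return 100.0 * luc_free / total


def segregation_test(
    counts: Union[GenotypeCounts, Mapping[str, int]],
    expected_ratio: Sequence[float] = (1, 2, 1),
) -> dict:
    """Pearson chi-square goodness of fit against a Mendelian ratio.

    Returns {"chi2", "df", "p"}; df = number of categories - 1.
    """
    if isinstance(counts, GenotypeCounts):
        observed = list(counts.as_tuple())
    else:
        observed = [counts[k] for k in sorted(counts)]
    if len(observed) != len(expected_ratio):
        raise ValueError("counts and expected ratio have different lengths")
    total = sum(observed)
    if total < 1:
        raise ValueError("total count must be >= 1")
    ratio_sum = sum(expected_ratio)
    expected = [total * r / ratio_sum for r in expected_ratio]
    if any(e == 0 for e in expected):
        raise ValueError("zero expected count in ratio")
    chi2, p = stats.chisquare(observed, f_exp=expected)
    return {"chi2": float(chi2), "df": len(observed) - 1, "p": float(p)}


def fraction_percent(numerator: int, denominator: int, ndigits: int = 0) -> float:
    """Percentage rendering of a count fraction, round-half-to-even."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("need 0 <= numerator <= denominator")
    return round(100.0 * numerator / denominator, ndigits)
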