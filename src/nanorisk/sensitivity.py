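"""Rank-correlation sensitivity analysis of Monte Carlo runs.

Each input's influence on an output is measured by the Spearman rank
correlation between its draws and the output draws; the "contribution
share" is the normalised squared rank correlation (the tornado-chart
convention of spreadsheet risk tools), which sums to 100% over inputs by
construction.  Being rank-based, the measure is invariant to strictly
monotone transforms of the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, UndefinedSensitivityError

MIN_SAMPLES = 30


@dataclass
class SensitivityReport:
    """Per-parameter rank correlations and contribution shares.

    ``table`` columns: parameter, rho, share_pct, constant_input (flag);
    rows sorted by |rho| descending, ties broken by parameter name.
    """

    table: pd.DataFrame

    @property
    def ranking(self) -> list[str]:
        return list(self.table["parameter"])

    def share(self, parameter: str) -> float:
        row = self.table[self.table["parameter"] == parameter]
        if row.empty:
            raise KeyError(parameter)
        return float(row["share_pct"].iloc[0])

    def to_text_bars(self, width: int = 40) -> str:
        """Plain-text tornado chart."""
        lines = []
        for _, row in self.table.iterrows():
            bar = "#" * max(1, int(round(abs(row.rho) * width))) if row.rho else ""
            lines.append(f"{row.parameter:>16s} {row.rho:+.3f} {row.share_pct:6.2f}% {bar}")
        return "\n".join(lines)


def rank_sensitivity(input_draws, output_draws, parameter_names=None) -> SensitivityReport:
    """Spearman rank correlation of each input column with the output.

    ``input_draws`` is (n, p); ``output_draws`` length n.  Constant input
    columns get rho = 0 with a flag; a constant output is an error because
    ranks are undefined.  Ties in ranks use average ranking.
    """
    x = np.asarray(input_draws, dtype=float)
    y = np.asarray(output_draws, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if n == 0 or y.size == 0:
        raise EmptyInputError("no draws supplied")
    if y.shape != (n,):
        raise EmptyInputError("output length must match input rows")
    if n < MIN_SAMPLES:
        raise EmptyInputError(f"need >= {MIN_SAMPLES} draws, got {n}")
    if np.ptp(y) == 0:
        raise UndefinedSensitivityError("output is constant; sensitivity undefined")
    if parameter_names is None:
        parameter_names = [f"x{i+1}" for i in range(p)]
    if len(parameter_names) != p:
        raise EmptyInputError("one name per input column required")

    rhos = np.zeros(p)
    constant = np.zeros(p, dtype=bool)
    for j in range(p):
        if np.ptp(x[:, j]) == 0:
            constant[j] = True
        else:
            rhos[j] = stats.spearmanr(x[:, j], y).statistic
    sq = rhos**2
    total = sq.sum()
    shares = sq / total * 100.0 if total > 0 else np.zeros(p)

    df = pd.DataFrame({
        "parameter": parameter_names,
        "rho": rhos,
        "share_pct": shares,
        "constant_input": constant,
    })
    df = df.sort_values(["rho", "parameter"],
                        key=lambda s: -s.abs() if s.name == "rho" else s,
                        kind="mergesort").reset_index(drop=True)
    return SensitivityReport(table=df)
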