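"""Machine-readable result tables plus a reproducibility run log.

Given any combination of lag tables, fitted models and rank-consistency
tables, writes delimited-text artefacts into an output directory:

* ``lags_<label>.csv``     — pairwise lag matrix rows (level_i, level_j,
  lag, CI, penalized CI, significance);
* ``exceedance_<label>.csv`` — P(score >= stage) curves per factor level;
* ``rank_consistency.csv`` — sites × year-pairs Spearman table;
* ``coefficients_<label>.csv`` / ``summary_<label>.txt`` — per fitted model;
* ``runlog.json``          — seed, options, package version.

The run log carries no timestamps, so identical inputs and seed produce
byte-identical output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .lags import lag_table_frame
from .ranks import consistency_frame

__all__ = ["write_report"]


def _exceedance_frame(results, stage, time_values) -> pd.DataFrame:
    rows = []
    factor = "site" if "site" in results.design.levels else list(results.design.levels)[0]
    others = {f: lv[0] for f, lv in results.design.levels.items() if f != factor}
    for level in results.design.levels[factor]:
        curve = results.exceedance_curve(stage, time_values, **{factor: level, **others})
        for t, p in curve.items():
            rows.append({factor: level, results.design.spec.time_term: t,
                         "stage": stage, "prob": p})
    return pd.DataFrame(rows)


def write_report(out_dir, lag_tables: dict | None = None,
                 fits: dict | None = None, rank_tables: list | None = None,
                 stage: int = 5, seed=None, options: dict | None = None) -> list[Path]:
    """Write every supplied result as delimited text; error when empty.

    ``lag_tables``: label -> list of TimeLagEstimate. ``fits``: label ->
    CumulativeLinkResults. ``rank_tables``: list of RankConsistencyTable.
    Returns the paths written.
    """
    if not (lag_tables or fits or rank_tables):
        raise ValueError("no results to report; nothing written")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for label, ests in (lag_tables or {}).items():
        p = out / f"lags_{label}.csv"
        lag_table_frame(ests).to_csv(p, index=False, float_format="%.6g")
        written.append(p)

    for label, res in (fits or {}).items():
        p = out / f"coefficients_{label}.csv"
        coefs = res.params.rename("estimate").to_frame()
        if res.vcov is not None:
            coefs["std_err"] = res.bse
        coefs.index.name = "parameter"
        coefs.to_csv(p, float_format="%.6g")
        written.append(p)
        ps = out / f"summary_{label}.txt"
        ps.write_text(res.summary() + "\n")
        written.append(ps)
        tvals = np.arange(1, 62)
        if res.design.spec.time_term != "day":
            lo = float(min(res.design.X[:, 0]))
            hi = float(max(res.design.X[:, 0]))
            tvals = np.linspace(lo, hi, 61)
        pe = out / f"exceedance_{label}.csv"
        _exceedance_frame(res, stage, tvals).to_csv(pe, index=False,
                                                    float_format="%.6g")
        written.append(pe)

    if rank_tables:
        p = out / "rank_consistency.csv"
        consistency_frame(rank_tables).to_csv(p, index=False, float_format="%.6g")
        written.append(p)

    log = {"seed": seed, "options": options or {}, "version": __version__,
           "files": [f.name for f in written]}
    plog = out / "runlog.json"
    plog.write_text(json.dumps(log, indent=2, sort_keys=True, default=str) + "\n")
    written.append(plog)
    return written
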