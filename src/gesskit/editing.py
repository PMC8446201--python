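"""Editing of raw insemination/calving logs into analysis-ready traits.

Rules implemented:

* Conception rate (CR): within a cow-parity, the last insemination before a
  positive pregnancy diagnosis is coded 1, all other inseminations 0.  A cow
  with a calving but no positive diagnosis is considered pregnant at her
  last insemination before that calving.
* 56-day non-return rate (NRR56): an insemination is coded 1 when no
  re-insemination occurs within 56 days, 0 when the return falls at 18-56
  days, and is excluded when the next insemination falls within 1-17 days
  (interpreted as the closed interval [1, 17]) or when neither a later
  insemination nor a calving exists after the 56-day window.
* Calving records: gestation lengths below 260 or above 302 days are
  deleted (260 and 302 retained); calving-ease scores outside {1,2,3} and
  stillbirth codes outside {1,2} are deleted as structurally ambiguous;
  calf-size groups are binned from birth weight at 30-40/40-50/50-60 kg and
  records outside 30-60 kg are dropped.

Every removed or flagged record is written to an audit list with the rule
that removed it; editing is idempotent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["assign_conception", "compute_nrr56", "edit_calving", "edit_records"]

GL_MIN = 260
GL_MAX = 302
NRR_WINDOW = 56
EARLY_RETURN_MAX = 17


def _audit(audit: list | None, rule: str, **info) -> None:
    if audit is not None:
        audit.append({"rule": rule, **info})


def assign_conception(events: pd.DataFrame, audit: list | None = None) -> pd.DataFrame:
    """Assign CR codes to inseminations from a per-cow event log.

    Parameters
    ----------
    events : DataFrame
        Columns ``cow``, ``parity``, ``event`` in {"insemination",
        "diagnosis_positive", "calving"}, ``date`` (sortable).  Extra
        columns are carried through for insemination rows.
    audit : list, optional
        Mutable audit log; dropped records are appended with their rule.

    Returns
    -------
    DataFrame of insemination rows with a ``cr`` column in {0, 1}.
    """
    events = events.sort_values(["cow", "parity", "date"], kind="stable")
    out = []
    for (cow, parity), grp in events.groupby(["cow", "parity"], sort=False):
        ins = grp[grp["event"] == "insemination"].copy()
        if ins.empty:
            continue
        diag = grp.loc[grp["event"] == "diagnosis_positive", "date"]
        calv = grp.loc[grp["event"] == "calving", "date"]
        ins["cr"] = 0
        target_date = None
        if not diag.empty:
            target_date = diag.iloc[0]
        elif not calv.empty:
            target_date = calv.iloc[0]
        if target_date is not None:
            before = ins[ins["date"] < target_date]
            if before.empty:
                _audit(
                    audit,
                    "conception_before_any_insemination",
                    cow=cow,
                    parity=parity,
                )
                continue
            ins.loc[before.index[-1], "cr"] = 1
        out.append(ins)
    if not out:
        return events.iloc[0:0].assign(cr=pd.Series(dtype=int))
    return pd.concat(out, ignore_index=True)


def compute_nrr56(events: pd.DataFrame, audit: list | None = None) -> pd.DataFrame:
    """Assign NRR56 codes (1/0/missing) to inseminations.

    Codes per insemination: 1 if no re-insemination within 56 days and a
    later event (insemination after the window, or any calving after the
    service) confirms the cow stayed under observation; 0 if the next
    insemination falls 18-56 days later; missing (NaN) if the next
    insemination falls within 1-17 days or no later event of any kind
    exists.  Duplicate same-day inseminations are collapsed to one.
    """
    events = events.sort_values(["cow", "date"], kind="stable")
    out = []
    for cow, grp in events.groupby("cow", sort=False):
        ins = grp[grp["event"] == "insemination"].copy()
        if ins.empty:
            continue
        dup = ins["date"].duplicated()
        if dup.any():
            for d in ins.loc[dup, "date"]:
                _audit(audit, "duplicate_same_day_insemination", cow=cow, date=d)
            ins = ins[~dup].copy()
        calv = grp.loc[grp["event"] == "calving", "date"]
        dates = list(ins["date"])
        codes: list = []
        for k, d0 in enumerate(dates):
            nxt = dates[k + 1] if k + 1 < len(dates) else None
            gap = None if nxt is None else (nxt - d0).days
            if gap is not None and 1 <= gap <= EARLY_RETURN_MAX:
                _audit(audit, "early_return_1_17d", cow=cow, date=d0)
                codes.append(np.nan)
            elif gap is not None and gap <= NRR_WINDOW:
                codes.append(0.0)
            else:
                # no return within 56 d: require evidence of later observation
                later_calving = (calv > d0).any()
                if gap is not None or later_calving:
                    codes.append(1.0)
                else:
                    _audit(audit, "no_later_event_after_window", cow=cow, date=d0)
                    codes.append(np.nan)
        ins["nrr56"] = codes
        out.append(ins)
    if not out:
        return events.iloc[0:0].assign(nrr56=pd.Series(dtype=float))
    return pd.concat(out, ignore_index=True)


def edit_calving(records: pd.DataFrame, audit: list | None = None) -> pd.DataFrame:
    """Filter raw calving records and bin calf size groups.

    Expects columns ``gl`` (gestation length, days), ``ce`` (1-3), ``sb``
    (1-2) and either ``calf_size_group`` or ``birth_weight`` (kg).
    """
    rec = records.copy()
    keep = pd.Series(True, index=rec.index)

    bad_gl = (rec["gl"] < GL_MIN) | (rec["gl"] > GL_MAX)
    for i in rec.index[bad_gl]:
        _audit(audit, "gl_out_of_bounds", row=int(i), gl=float(rec.loc[i, "gl"]))
    keep &= ~bad_gl

    if "ce" in rec.columns:
        bad_ce = ~rec["ce"].isin([1, 2, 3])
        for i in rec.index[bad_ce & keep]:
            _audit(audit, "ambiguous_ce_code", row=int(i), ce=rec.loc[i, "ce"])
        keep &= ~bad_ce
    if "sb" in rec.columns:
        bad_sb = ~rec["sb"].isin([1, 2])
        for i in rec.index[bad_sb & keep]:
            _audit(audit, "ambiguous_sb_code", row=int(i), sb=rec.loc[i, "sb"])
        keep &= ~bad_sb

    rec = rec[keep].copy()
    if "calf_size_group" not in rec.columns:
        if "birth_weight" not in rec.columns:
            raise ValueError("need calf_size_group or birth_weight column")
        w = rec["birth_weight"].astype(float)
        out_of_range = (w < 30) | (w > 60)
        for i in rec.index[out_of_range]:
            _audit(
                audit,
                "birth_weight_out_of_range",
                row=int(i),
                birth_weight=float(w.loc[i]),
            )
        rec = rec[~out_of_range].copy()
        w = rec["birth_weight"].astype(float)
        rec["calf_size_group"] = pd.cut(
            w,
            bins=[30, 40, 50, 60],
            labels=["30-40", "40-50", "50-60"],
            include_lowest=True,
        ).astype(str)
    return rec.reset_index(drop=True)


def edit_records(
    events: pd.DataFrame,
    calvings: pd.DataFrame | None = None,
    audit: list | None = None,
) -> dict:
    """Run the full editing layer; returns dict of edited tables.

    ``events`` feeds CR and NRR56 coding; ``calvings`` (optional) feeds the
    calving-trait filters.  The shared audit list records every drop.
    """
    out = {
        "cr": assign_conception(events, audit=audit),
        "nrr56": compute_nrr56(events, audit=audit),
    }
    if calvings is not None:
        out["calving"] = edit_calving(calvings, audit=audit)
    return out
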