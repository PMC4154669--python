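"""Scoring of pipeline output against the simulator's ground truth."""

from __future__ import annotations

import pandas as pd


def _assigned_tissue(tstrs: pd.DataFrame, chrom: str, start: int,
                     end: int) -> str:
    hit = tstrs[(tstrs["chrom"] == chrom) & (tstrs["start"] < end)
                & (tstrs["end"] > start)]
    if not len(hit):
        return "missed"
    return hit.iloc[0]["tissue"]


def score_recovery(tstrs: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Sensitivity on planted tissue-specific loci and the call rate on
    planted non-specific loci.

    A specific locus counts as recovered when some called region overlapping
    it is assigned to the locus's active tissue; a non-specific locus counts
    as a false call when any overlapping region is assigned to either tissue.
    """
    calls = [
        _assigned_tissue(tstrs, row.chrom, row.start, row.end)
        for row in truth.itertuples(index=False)]
    truth = truth.assign(called=calls)
    specific = truth[truth["specific"] == 1]
    nonspecific = truth[truth["specific"] == 0]
    sensitivity = (float((specific["called"]
                          == specific["active_tissue"]).mean())
                   if len(specific) else float("nan"))
    false_rate = (float((~nonspecific["called"]
                         .isin(["none", "missed"])).mean())
                  if len(nonspecific) else float("nan"))
    return {"sensitivity": sensitivity, "false_call_rate": false_rate,
            "n_specific": int(len(specific)),
            "n_nonspecific": int(len(nonspecific))}
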