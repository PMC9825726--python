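"""Sliding-window recombination screening.

A query row of a multiple alignment is compared against candidate donor
reference rows in overlapping windows; a sustained switch of the most
similar reference calls a crossover, in the spirit of similarity-plot
recombination analysis tools. Hysteresis (a margin plus a minimum run of
supporting windows) suppresses jitter where references are nearly
equidistant.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consensus import MultipleAlignment
from .errors import InputError

MIN_USABLE_SITES = 10


@dataclass
class SimilarityProfile:
    query_id: str
    reference_ids: list[str]
    window: int
    step: int
    values: np.ndarray  # (n_windows, n_references); NaN = missing window
    window_starts: np.ndarray  # alignment column of each window start
    query_positions: np.ndarray  # ungapped query coordinate at each window start

    @property
    def window_centers(self) -> np.ndarray:
        return self.window_starts + self.window // 2


@dataclass(frozen=True)
class RecombinationEvent:
    query_id: str
    donor_before: str
    donor_inside: str
    breakpoint_start: int  # alignment columns, window resolution
    breakpoint_end: int
    support: int  # consecutive windows backing the new donor
    query_breakpoint_start: int = 0  # same interval in ungapped query coords
    query_breakpoint_end: int = 0


def sliding_similarity(aln: MultipleAlignment, query_id: str,
                       reference_ids: list[str], window: int = 200,
                       step: int = 50) -> SimilarityProfile:
    """Per-window identity fraction between the query and each reference.

    Identity is computed over columns where both rows have an unambiguous
    base; windows with fewer than 10 such sites are flagged missing (NaN)
    rather than scored 0.
    """
    if window < 20:
        raise InputError("window must be >= 20 columns")
    if step > window or step < 1:
        raise InputError("step must be in [1, window]")
    if len(reference_ids) < 1:
        raise InputError("at least one reference required")
    mat = aln.matrix()
    try:
        qi = aln.member_ids.index(query_id)
    except ValueError:
        raise LookupError(f"query {query_id!r} not in alignment") from None
    ref_idx = []
    for rid in reference_ids:
        try:
            ref_idx.append(aln.member_ids.index(rid))
        except ValueError:
            raise LookupError(f"reference {rid!r} not in alignment") from None
    q = mat[qi]
    q_ok = q < 4
    n_cols = aln.n_columns
    starts = np.arange(0, max(1, n_cols - window + 1), step)
    values = np.full((starts.size, len(ref_idx)), np.nan)
    for rj, ri in enumerate(ref_idx):
        r = mat[ri]
        ok = q_ok & (r < 4)
        eq = ok & (q == r)
        ok_cum = np.concatenate([[0], np.cumsum(ok)])
        eq_cum = np.concatenate([[0], np.cumsum(eq)])
        usable = ok_cum[starts + window] - ok_cum[starts]
        matches = eq_cum[starts + window] - eq_cum[starts]
        good = usable >= MIN_USABLE_SITES
        values[good, rj] = matches[good] / usable[good]
    q_nongap_cum = np.concatenate([[0], np.cumsum(q < 5)])
    query_positions = q_nongap_cum[starts]
    return SimilarityProfile(query_id=query_id, reference_ids=list(reference_ids),
                             window=window, step=step, values=values,
                             window_starts=starts,
                             query_positions=query_positions.astype(int))


def detect_crossovers(profile: SimilarityProfile, min_support: int = 3,
                      margin: float = 0.05) -> list[RecombinationEvent]:
    """Call donor switches from a similarity profile.

    The nearest reference per window is the identity arg-max (ties break by
    reference input order). A crossover is called when the nearest reference
    changes and the challenger stays nearest — exceeding the previous donor
    by at least ``margin`` — for at least ``min_support`` consecutive
    windows. The breakpoint interval spans from the start of the last window
    won by the old donor to the end of the first window of the new donor's
    run.
    """
    if len(profile.reference_ids) < 2:
        raise InputError("crossover detection needs >= 2 references")
    vals = profile.values
    valid = ~np.all(np.isnan(vals), axis=1)
    idx = np.nonzero(valid)[0]
    if idx.size == 0:
        return []
    nearest = np.full(vals.shape[0], -1)
    nearest[idx] = np.nanargmax(vals[idx], axis=1)
    events: list[RecombinationEvent] = []
    order = list(idx)
    current = int(nearest[order[0]])
    last_current_win = order[0]
    i = 1
    while i < len(order):
        w = order[i]
        cand = int(nearest[w])
        if cand == current:
            last_current_win = w
            i += 1
            continue
        # measure the challenger's run with margin over the old donor
        run = 0
        j = i
        while j < len(order):
            wj = order[j]
            if (int(nearest[wj]) == cand
                    and vals[wj, cand] - vals[wj, current] >= margin):
                run += 1
                j += 1
            else:
                break
        if run >= min_support:
            w_end = profile.window_starts[w] + profile.window
            events.append(RecombinationEvent(
                query_id=profile.query_id,
                donor_before=profile.reference_ids[current],
                donor_inside=profile.reference_ids[cand],
                breakpoint_start=int(profile.window_starts[last_current_win]),
                breakpoint_end=int(w_end),
                support=run,
                query_breakpoint_start=int(profile.query_positions[last_current_win]),
                query_breakpoint_end=int(min(
                    profile.query_positions[w] + profile.window,
                    profile.query_positions[-1] + profile.window)),
            ))
            current = cand
            last_current_win = order[j - 1]
            i = j
        else:
            i += 1
    return events


def write_profile(profile: SimilarityProfile, path) -> None:
    """Plain-text matrix of the profile for downstream plotting."""
    with open(path, "w") as fh:
        fh.write("window_start\tquery_pos\t" + "\t".join(profile.reference_ids) + "\n")
        for i, s in enumerate(profile.window_starts):
            row = "\t".join("NA" if np.isnan(v) else f"{v:.4f}"
                            for v in profile.values[i])
            fh.write(f"{s}\t{profile.query_positions[i]}\t{row}\n")
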