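"""Rule-based refinement of genotype calls along the map order.

Two passes produce homogeneous haplotype blocks.  First, mosaic regions --
stretches of 12 or more consecutive loci in which every call differs from the
previous one -- are wiped to no-call.  Second, each locus that disagrees with
its immediate neighborhood is re-examined: six or more consecutive uniform
same-call loci on BOTH sides with a common call overwrite the locus; flanks
that disagree or are non-uniform set it to no-call.  Loci within one flank of
a chromosome end, and loci matching a uniform flank of their own call (i.e.
clean recombination breakpoints), are never modified.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import NC


def _runs(seq: np.ndarray):
    """Run-length encoding: list of (value, start, length)."""
    out = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            out.append((seq[start], start, i - start))
            start = i
    return out


def refine_region(seq, region_len: int = 12):
    """Set mosaic stretches of >= ``region_len`` loci to no-call.

    A mosaic stretch is a maximal run of singleton calls (each locus differing
    from its predecessor and successor), i.e. a region "stretched out over
    different consecutive calls"; its length counts loci.
    """
    arr = np.asarray(seq, dtype=object).copy()
    runs = _runs(arr)
    i = 0
    while i < len(runs):
        if runs[i][2] == 1:
            j = i
            while j + 1 < len(runs) and runs[j + 1][2] == 1:
                j += 1
            n_loci = j - i + 1
            if n_loci >= region_len:
                start = runs[i][1]
                arr[start:start + n_loci] = NC
            i = j + 1
        else:
            i += 1
    return arr


def _uniform(window: np.ndarray):
    """The common non-NC value of a window, or None."""
    v = window[0]
    if v == NC:
        return None
    return v if (window == v).all() else None


def refine_locus(seq, flank: int = 6):
    """Re-call or no-call loci that disagree with their flanking loci.

    Decisions are made against the input sequence and applied simultaneously.
    A locus is examined when it differs from at least one immediate neighbor;
    it is left alone when either ``flank``-window is uniformly its own call
    (clean breakpoints survive) and when an immediate neighbor is itself a
    no-call (the uncertainty boundary is not advanced, which also makes the
    pass idempotent).  Uniform windows of a common other call overwrite the
    locus; anything else (disagreeing or non-uniform flanks) yields a no-call.
    """
    arr = np.asarray(seq, dtype=object)
    out = arr.copy()
    n = len(arr)
    for i in range(flank, n - flank):
        c = arr[i]
        if arr[i - 1] == c and arr[i + 1] == c:
            continue
        if c != NC and (arr[i - 1] == NC or arr[i + 1] == NC):
            continue
        left = _uniform(arr[i - flank:i])
        right = _uniform(arr[i + 1:i + 1 + flank])
        if (left is not None and left == c) or (right is not None and right == c):
            continue  # consistent with one flank (e.g. a clean breakpoint)
        if left is not None and right is not None and left == right:
            out[i] = left
        else:
            out[i] = NC
    return out


def refine_sequence(seq, flank: int = 6, region_len: int = 12,
                    max_passes: int = 10):
    """Region rule first (the larger pathology), then the locus rule,
    iterated to a fixpoint.

    A locus pass can itself create a new mosaic stretch (singletons turned to
    no-call next to other singletons), so the pair of rules is repeated until
    the sequence stops changing (almost always one or two passes; capped).
    """
    cur = np.asarray(seq, dtype=object)
    for _ in range(max_passes):
        nxt = refine_locus(refine_region(cur, region_len), flank)
        if (nxt == cur).all():
            break
        cur = nxt
    return cur


def refine_calls(
    calls: pd.DataFrame, order: list[str], flank: int = 6, region_len: int = 12,
) -> pd.DataFrame:
    """Refine every sample's call sequence along one linkage group's order.

    Returns a copy of ``calls`` restricted to ``order`` with refined values;
    markers not in the order are untouched.
    """
    sub = calls.loc[order]
    refined = sub.copy()
    for sample in sub.columns:
        refined[sample] = refine_sequence(sub[sample].to_numpy(), flank, region_len)
    return refined


def refine_map_calls(
    calls: pd.DataFrame, orders: dict[int, list[str]],
    flank: int = 6, region_len: int = 12,
) -> pd.DataFrame:
    """Apply refinement per linkage group; returns the full refined matrix."""
    out = calls.copy()
    for order in orders.values():
        present = [m for m in order if m in out.index]
        if len(present) > 1:
            out.loc[present] = refine_calls(out, present, flank, region_len)
    return out


def count_nc_regions(seq) -> int:
    """Number of maximal runs of consecutive no-calls."""
    arr = np.asarray(seq, dtype=object)
    is_nc = arr == NC
    if len(arr) == 0:
        return 0
    starts = is_nc & ~np.concatenate([[False], is_nc[:-1]])
    return int(starts.sum())


def nc_regions_per_sample(
    calls: pd.DataFrame, orders: dict[int, list[str]],
) -> pd.Series:
    """Total no-call region count per sample, summed over linkage groups."""
    totals = pd.Series(0, index=calls.columns)
    for order in orders.values():
        present = [m for m in order if m in calls.index]
        sub = calls.loc[present]
        for sample in calls.columns:
            totals[sample] += count_nc_regions(sub[sample].to_numpy())
    return totals


def refinement_diff(before: pd.DataFrame, after: pd.DataFrame) -> pd.DataFrame:
    """Long-format (sample, marker, old, new) table of changed calls."""
    common = before.index.intersection(after.index)
    b = before.loc[common]
    a = after.loc[common]
    changed = b != a
    rows = []
    for marker in common:
        for sample in b.columns[changed.loc[marker].to_numpy()]:
            rows.append((sample, marker, b.at[marker, sample], a.at[marker, sample]))
    return pd.DataFrame(rows, columns=["sample", "marker", "old", "new"])
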