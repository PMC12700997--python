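"""Independent brute-force oracles used by the test suite.

Everything here applies definitions directly (exhaustive enumeration,
double loops, literal tallies) and shares no code with the implementation
paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def tree_arrays(tree):
    """(tips, internals, edges) with edges as (child, parent) node-id pairs."""
    tips = tree.tips
    internals = [n for n in tree.postorder() if not tree.is_tip(n)]
    edges = [(n, tree.parent[n]) for n in tree.postorder() if tree.parent[n] is not None]
    return tips, internals, edges


def exhaustive_fitch(tree, tip_states):
    """Minimum state changes by enumerating every ancestral labeling."""
    tips, internals, edges = tree_arrays(tree)
    best = len(edges) + 1
    for assignment in itertools.product((0, 1), repeat=len(internals)):
        lab = dict(zip(internals, assignment))
        lab.update(tip_states)
        changes = sum(lab[c] != lab[p] for c, p in edges)
        best = min(best, changes)
    return best


def exhaustive_parsimony_all_patterns(tree):
    """Per-pattern (fitch_min, dollo_min_losses) for ALL 2^n tip patterns.

    Vectorized enumeration over all internal labelings. Dollo restricts to
    histories with exactly one gain (root presence counts as the gain);
    the all-absent pattern gets 0 losses by convention (never gained).
    Pattern index encodes tip states bitwise in ``tree.tips`` order.
    """
    tips, internals, edges = tree_arrays(tree)
    n, m = len(tips), len(internals)
    P = (np.arange(2**n)[:, None] >> np.arange(n)) & 1  # patterns × tips
    L = (np.arange(2**m)[:, None] >> np.arange(m)) & 1  # labelings × internals
    tip_idx = {t: i for i, t in enumerate(tips)}
    int_idx = {x: i for i, x in enumerate(internals)}

    changes = np.zeros((2**n, 2**m), dtype=np.int32)
    gains = np.zeros((2**n, 2**m), dtype=np.int32)
    losses = np.zeros((2**n, 2**m), dtype=np.int32)

    def states(node):
        if node in tip_idx:
            return P[:, tip_idx[node]][:, None]  # patterns × 1
        return L[:, int_idx[node]][None, :]  # 1 × labelings

    for child, parent in edges:
        cs, ps = states(child), states(parent)
        changes += cs != ps
        gains += (ps == 0) & (cs == 1)
        losses += (ps == 1) & (cs == 0)
    gains += states(tree.root) == 1  # gain on the root stem

    fitch_min = changes.min(axis=1)
    masked = np.where(gains == 1, losses, np.iinfo(np.int32).max)
    dollo_min = masked.min(axis=1)
    dollo_min[0] = 0  # all-absent: no gain, no losses
    return fitch_min, dollo_min


def brute_force_rbh(ab_rows, ba_rows, evalue_max=1e-3):
    """RBH by literal definition: double loop over queries of both tables.

    Rows are (query, subject, bitscore, evalue) tuples.
    """

    def best(rows, q):
        cand = [r for r in rows if r[0] == q and r[3] <= evalue_max]
        if not cand:
            return None
        cand.sort(key=lambda r: (-r[2], r[3], r[1]))
        return cand[0][1]

    queries_a = {r[0] for r in ab_rows}
    pairs = set()
    for a in queries_a:
        b = best(ab_rows, a)
        if b is not None and best(ba_rows, b) == a:
            pairs.add((a, b))
    return pairs


def brute_force_histogram(values, bin_width, overflow_threshold):
    """Literal tally into half-open bins plus an overflow bucket."""
    n_bins = int(np.ceil(overflow_threshold / bin_width))
    counts = [0] * n_bins
    overflow = 0
    for v in values:
        if v >= overflow_threshold:
            overflow += 1
        else:
            for k in range(n_bins):
                if k * bin_width <= v < (k + 1) * bin_width:
                    counts[k] += 1
                    break
    return counts, overflow


def brute_force_clade_means(presence, clade_map):
    """Group-by mean via explicit loops; presence is a pandas bool frame."""
    out = {}
    for clade in sorted(set(clade_map.values())):
        members = [g for g in presence.index if clade_map[g] == clade]
        out[clade] = {
            fam: sum(bool(presence.loc[g, fam]) for g in members) / len(members)
            for fam in presence.columns
        }
    return out


def brute_force_pathway(ko_set, steps):
    """steps: {name: [alternative sets]}; literal evaluation."""
    have = set(ko_set)
    hits = {
        name: any(set(alt) <= have for alt in alts) for name, alts in steps.items()
    }
    return sum(hits.values()) / len(hits), hits


def brute_force_adjacency(a_families, b_families, shared):
    """Adjacency conservation count by scanning both orders literally."""
    b_pairs = set()
    for i in range(len(b_families) - 1):
        b_pairs.add((b_families[i], b_families[i + 1]))
        b_pairs.add((b_families[i + 1], b_families[i]))
    pairs = [
        (a_families[i], a_families[i + 1])
        for i in range(len(a_families) - 1)
        if a_families[i] in shared and a_families[i + 1] in shared
    ]
    if not pairs:
        return 0.0
    return sum(p in b_pairs for p in pairs) / len(pairs)


def brute_force_independent_events(edges, tree):
    """Count events after removing any event nested below another event."""
    kept = []
    for e in edges:
        nested = False
        for other in edges:
            if other == e:
                continue
            node = tree.parent.get(e)
            while node is not None:
                if node == other:
                    nested = True
                    break
                node = tree.parent.get(node)
            if nested:
                break
        if not nested:
            kept.append(e)
    return len(set(kept))
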