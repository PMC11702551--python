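"""Slow, independent reference implementations used as test oracles.

Deliberately written with plain Python loops from first principles, sharing
no code paths with the package: exhaustive pairwise sorting, dictionary
bookkeeping, and direct formula evaluation only.
"""

import math


def ref_rmsd(a, b):
    assert len(a) == len(b) > 0
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / len(a))


def ref_similarity_lists(ids, scores):
    """ids: list of str; scores: list of row-lists. -> {id: [(other, dist, rank)]}"""
    sig = dict(zip(ids, scores))
    out = {}
    for me in ids:
        pairs = sorted(
            ((ref_rmsd(sig[me], sig[other]), other) for other in ids if other != me)
        )
        out[me] = [(other, d, r) for r, (d, other) in enumerate(pairs, start=1)]
    return out


def ref_consensus(seeds, lists, cutoff, candidates):
    """Exhaustive consensus ordering.

    lists: output of ref_similarity_lists. Returns ordered list of
    (candidate, count, mean_cutoff_rank, mean_full_rank, mean_distance).
    """
    stats = []
    for cand in candidates:
        in_cutoff, full_ranks, dists = [], [], []
        for seed in seeds:
            if seed == cand:
                continue  # a compound never appears in its own list
            for other, dist, rank in lists[seed]:
                if other == cand:
                    full_ranks.append(rank)
                    dists.append(dist)
                    if rank <= cutoff:
                        in_cutoff.append(rank)
                    break
        count = len(in_cutoff)
        mcr = sum(in_cutoff) / count if count else math.inf
        mfr = sum(full_ranks) / len(full_ranks) if full_ranks else math.inf
        mdist = sum(dists) / len(dists) if dists else math.inf
        stats.append((cand, count, mcr, mfr, mdist))
    stats.sort(key=lambda t: (-t[1], t[2], t[3], t[4], t[0]))
    return stats


def ref_loo_rank(drugs, withheld, lists, cutoff, candidates):
    seeds = sorted(set(drugs) - {withheld})
    order = ref_consensus(seeds, lists, cutoff, candidates)
    for pos, (cand, *_rest) in enumerate(order, start=1):
        if cand == withheld:
            return pos
    raise AssertionError("withheld drug not among candidates")


def ref_dcg(rank):
    return 1.0 / math.log2(rank + 1)


def ref_original_ia(drugs, lists, rank_cutoff):
    hits = 0
    for drug in drugs:
        ranked = {other: rank for other, _d, rank in lists[drug]}
        if any(
            ranked.get(o, math.inf) <= rank_cutoff for o in drugs if o != drug
        ):
            hits += 1
    return 100.0 * hits / len(drugs)


def ref_benchmark(mapping, ids, scores, cutoff, rank_cutoffs, candidates=None):
    """Full leave-one-out benchmark from first principles.

    mapping: {indication: set of drugs}. Returns (naia, nndcg, nndcg_overall,
    aia, per_indication) where per_indication maps indication ->
    {"ranks": {drug: rank}, "nia": {...}, "nndcg": {...}, ...}.
    """
    lists = ref_similarity_lists(ids, scores)
    if candidates is None:
        candidates = sorted(ids)
    per_ind = {}
    for ind in sorted(mapping):
        drugs = sorted(mapping[ind])
        if len(drugs) < 2:
            continue
        ranks = {
            d: ref_loo_rank(drugs, d, lists, cutoff, candidates) for d in drugs
        }
        vals = list(ranks.values())
        nia = {
            k: 100.0 * sum(r <= k for r in vals) / len(vals) for k in rank_cutoffs
        }
        nndcg = {
            k: sum(ref_dcg(r) for r in vals if r <= k) / len(vals)
            for k in rank_cutoffs
        }
        overall = sum(ref_dcg(r) for r in vals) / len(vals)
        ia = {k: ref_original_ia(drugs, lists, k) for k in rank_cutoffs}
        per_ind[ind] = {
            "ranks": ranks, "nia": nia, "nndcg": nndcg,
            "nndcg_overall": overall, "ia": ia,
        }
    n = len(per_ind)
    naia = {
        k: sum(v["nia"][k] for v in per_ind.values()) / n for k in rank_cutoffs
    }
    nndcg = {
        k: sum(v["nndcg"][k] for v in per_ind.values()) / n for k in rank_cutoffs
    }
    overall = sum(v["nndcg_overall"] for v in per_ind.values()) / n
    aia = {k: sum(v["ia"][k] for v in per_ind.values()) / n for k in rank_cutoffs}
    return naia, nndcg, overall, aia, per_ind
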