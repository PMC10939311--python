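"""Naive loop-based reference implementation of every success-rate metric.

Deliberately independent of the package internals: grouping is a dict of
tuples, aggregation is an explicit max loop, and every rate is computed by
filtering and counting with plain Python. Used only as an oracle in tests.
"""

from optoaudit.vocab import Domain, OutcomeLevel

ALL_DOMAINS = (Domain.HISTOLOGY, Domain.PHYSIOLOGY, Domain.BEHAVIOR)


def naive_groups(records):
    groups = {}
    for r in records:
        key = (r.lab_id, r.animal_id, r.region_canonical)
        groups.setdefault(key, []).append(r)
    return groups


def naive_agg(group, domain):
    best = OutcomeLevel.MISSING
    for r in group:
        if int(r.outcomes[domain]) > int(best):
            best = r.outcomes[domain]
    return best


def naive_domain_rate(records, domain, threshold):
    num = den = 0
    for group in naive_groups(records).values():
        agg = naive_agg(group, domain)
        if agg != OutcomeLevel.MISSING:
            den += 1
            if int(agg) >= int(threshold):
                num += 1
    return num, den


def naive_conjunction_rate(records, domains, threshold):
    num = den = 0
    for group in naive_groups(records).values():
        aggs = [naive_agg(group, d) for d in domains]
        if all(a != OutcomeLevel.MISSING for a in aggs):
            den += 1
            if all(int(a) >= int(threshold) for a in aggs):
                num += 1
    return num, den


def naive_injection_rate(records, threshold):
    num = den = 0
    for r in records:
        levels = [r.outcomes[d] for d in ALL_DOMAINS]
        if any(l != OutcomeLevel.MISSING for l in levels):
            den += 1
            if any(int(l) >= int(threshold) for l in levels):
                num += 1
    return num, den


def naive_figure1(records):
    counts = {d: {level: 0 for level in OutcomeLevel} for d in ALL_DOMAINS}
    for group in naive_groups(records).values():
        for d in ALL_DOMAINS:
            counts[d][naive_agg(group, d)] += 1
    return counts


def naive_figure2(records):
    out = {}
    for pair in ((Domain.BEHAVIOR, Domain.PHYSIOLOGY), (Domain.BEHAVIOR, Domain.HISTOLOGY)):
        label = "+".join(sorted(d.value for d in pair))
        any_n, total = naive_conjunction_rate(records, pair, OutcomeLevel.WEAK)
        strong_n, _ = naive_conjunction_rate(records, pair, OutcomeLevel.STRONG)
        out[label] = (total, any_n, strong_n)
    return out
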