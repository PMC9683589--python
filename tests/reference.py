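"""Plain-loop reference implementations used as independent oracles.

Everything here is deliberately written with explicit Python loops and
sorting, no vectorization and no calls into phaseslope internals, so the
package's statistics can be checked against an independent path.
"""

import math


def ref_bin(counts_rows, valid_flags, bin_minutes):
    """counts_rows: list of per-minute lists (one per minute), one column per fly."""
    n_flies = len(counts_rows[0])
    n_bins = len(counts_rows) // bin_minutes
    out = []
    for b in range(n_bins):
        rows = counts_rows[b * bin_minutes:(b + 1) * bin_minutes]
        flags = valid_flags[b * bin_minutes:(b + 1) * bin_minutes]
        n_invalid = sum(1 for f in flags if not f)
        if n_invalid / bin_minutes > 0.5:
            out.append([math.nan] * n_flies)
            continue
        bin_vals = []
        for j in range(n_flies):
            total = 0
            for row, f in zip(rows, flags):
                if f:
                    total += row[j]
            bin_vals.append(float(total))
        out.append(bin_vals)
    return out


def ref_median(values):
    vals = sorted(v for v in values if not math.isnan(v))
    if not vals:
        return math.nan
    n = len(vals)
    if n % 2:
        return vals[n // 2]
    return 0.5 * (vals[n // 2 - 1] + vals[n // 2])


def ref_normalize(binned):
    """Percent of each fly's max bin; flies with zero max are dropped."""
    n_flies = len(binned[0])
    maxima = []
    for j in range(n_flies):
        col = [row[j] for row in binned if not math.isnan(row[j])]
        maxima.append(max(col) if col else 0.0)
    kept = [j for j in range(n_flies) if maxima[j] > 0]
    out = []
    for row in binned:
        out.append([row[j] / maxima[j] * 100.0 for j in kept])
    return out, kept


def ref_profile(norm_rows):
    return [ref_median(row) for row in norm_rows]


def ref_landmarks(zt, med, transition_zt):
    """Exhaustive scan: last bin attaining the min, then first attaining
    the max among strictly later pre-transition bins."""
    pre = [(t, m) for t, m in zip(zt, med) if t < transition_zt]
    lo = min(m for _, m in pre)
    zt_min = max(t for t, m in pre if m == lo)
    after = [(t, m) for t, m in pre if t > zt_min]
    hi = max(m for _, m in after)
    zt_max = min(t for t, m in after if m == hi)
    return zt_min, zt_max


def ref_slopes(zt, norm_rows, zt_min, zt_max):
    i1 = zt.index(min(zt_min, zt_max))
    i2 = zt.index(max(zt_min, zt_max))
    dt = abs(zt_max - zt_min)
    return [(norm_rows[i2][j] - norm_rows[i1][j]) / dt
            for j in range(len(norm_rows[0]))]


def ref_kruskal_h(groups):
    """Tie-corrected Kruskal-Wallis H from the textbook rank formula."""
    pooled = sorted((v, g) for g, vals in enumerate(groups) for v in vals)
    n = len(pooled)
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[j + 1][0] == pooled[i][0]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[k] = avg
        i = j + 1
    rank_sums = [0.0] * len(groups)
    for (v, g), r in zip(pooled, ranks):
        rank_sums[g] += r
    h = (12.0 / (n * (n + 1))
         * sum(rs ** 2 / len(groups[g]) for g, rs in enumerate(rank_sums))
         - 3 * (n + 1))
    ties = {}
    for v, _ in pooled:
        ties[v] = ties.get(v, 0) + 1
    correction = 1.0 - sum(t ** 3 - t for t in ties.values()) / (n ** 3 - n)
    return h / correction
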