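"""Independent brute-force reference implementations of the similarity
measures, used only to cross-check the package's vector/sparse versions.
Everything here works on plain dicts with explicit loops and closed-form
combinatorics — no shared code with dialib.similarity."""

import math


def dot_oracle(q: dict, l: dict) -> float:
    return sum(q[k] * l[k] for k in set(q) & set(l))


def libc_oracle(q: dict, l: dict) -> float:
    matched = [k for k in set(q) & set(l) if q[k] > 0 and l[k] > 0]
    if not matched:
        return 0.0
    num = sum(q[k] * l[k] for k in matched)
    q_norm = math.sqrt(sum(q[k] ** 2 for k in matched))
    l_norm = math.sqrt(sum(v ** 2 for v in l.values()))
    return num / (q_norm * l_norm)


def xcorr_oracle(q: dict, l: dict, window: int = 75) -> float:
    def shifted_dot(tau: int) -> float:
        return sum(qv * l.get(k - tau, 0.0) for k, qv in q.items())

    aligned = shifted_dot(0)
    background = sum(shifted_dot(t)
                     for t in range(-window, window + 1) if t != 0)
    return aligned - background / (2 * window)


def pcc_oracle(q: dict, l: dict) -> float:
    support = sorted(set(q) | set(l))
    if len(support) < 2:
        return 0.0
    x = [q.get(k, 0.0) for k in support]
    y = [l.get(k, 0.0) for k in support]
    n = len(support)
    mx, my = sum(x) / n, sum(y) / n
    sxx = sum((v - mx) ** 2 for v in x)
    syy = sum((v - my) ** 2 for v in y)
    if sxx == 0 or syy == 0:
        return 0.0
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    return sxy / math.sqrt(sxx * syy)


def kendall_oracle(q: dict, l: dict) -> float:
    """Kendall tau-b by explicit pair counting over matched bins."""
    matched = [k for k in set(q) & set(l) if q[k] > 0 and l[k] > 0]
    n = len(matched)
    if n < 2:
        return 0.0
    x = [q[k] for k in matched]
    y = [l[k] for k in matched]
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    if denom == 0:
        return 0.0
    return (concordant - discordant) / denom


def hgt_oracle(q: dict, l: dict) -> float:
    """-log10 of the exact hypergeometric tail sum."""
    qs = {k for k, v in q.items() if v > 0}
    ls = {k for k, v in l.items() if v > 0}
    if not qs or not ls:
        return 0.0
    union = qs | ls
    N = max(union) - min(union) + 1
    K, n, k = len(ls), len(qs), len(qs & ls)
    if k == 0:
        return 0.0
    tail = sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / math.comb(N, n)
    return max(0.0, -math.log10(min(tail, 1.0)))


def dot_bias_oracle(q: dict, l: dict) -> float:
    d = dot_oracle(q, l)
    if d == 0:
        return 0.0
    return math.sqrt(sum((q[k] * l[k]) ** 2 for k in set(q) & set(l))) / d
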