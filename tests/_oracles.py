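"""Independent brute-force oracles for cross-checking the fuzzy transforms.

Pure-python double loops, deliberately written without the package's
vectorised membership machinery so that agreement is meaningful.
"""

import math


def naive_membership(a: float, b: float, n: int, k: int, x: float) -> float:
    """Raised-cosine membership of node k (0-based) at x, from first principles."""
    h = (b - a) / (n - 1)
    nodes = [a + h * j for j in range(n)]
    nodes[-1] = b  # the last node IS b; a + h*(n-1) can land one ulp off
    lo = nodes[k - 1] if k > 0 else nodes[0]
    hi = nodes[k + 1] if k < n - 1 else nodes[n - 1]
    if x < lo or x > hi:
        return 0.0
    return 0.5 * (1.0 + math.cos(math.pi * (x - nodes[k]) / h))


def naive_components(a, b, n, points, values):
    """Order-0 and order-1 components by explicit double loops.

    Returns (F0, c0, c1) as plain lists; c1 falls back to 0 on a zero
    denominator, mirroring the unidentifiable-slope convention.
    """
    h = (b - a) / (n - 1)
    nodes = [a + h * j for j in range(n)]
    nodes[-1] = b
    F0, C0, C1 = [], [], []
    for k in range(n):
        num0 = den0 = num1 = den1 = 0.0
        for p, v in zip(points, values):
            w = naive_membership(a, b, n, k, p)
            num0 += v * w
            den0 += w
            num1 += v * (p - nodes[k]) * w
            den1 += (p - nodes[k]) ** 2 * w
        F0.append(num0 / den0)
        C0.append(num0 / den0)
        C1.append(num1 / den1 if den1 > 0.0 else 0.0)
    return F0, C0, C1


def naive_inverse_f1(a, b, n, c0, c1, x):
    """First-order reconstruction at a single point by explicit summation."""
    h = (b - a) / (n - 1)
    nodes = [a + h * j for j in range(n)]
    nodes[-1] = b
    num = den = 0.0
    for k in range(n):
        w = naive_membership(a, b, n, k, x)
        num += (c0[k] + c1[k] * (x - nodes[k])) * w
        den += w
    return num / den
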