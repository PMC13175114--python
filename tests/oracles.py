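"""Independent brute-force oracles, deliberately written without the package's
vectorized code paths: plain Python loops and math-module arithmetic."""

import math


def log_abf(beta, se, W):
    V = se * se
    z = beta / se
    return 0.5 * math.log(V / (V + W)) + 0.5 * z * z * (W / (V + W))


def bruteforce_single_causal_pp(beta_a, se_a, beta_b, se_b, W=0.0225,
                                priors=(1e-4, 1e-4, 1e-5)):
    """Five-hypothesis posterior by exhaustive single-causal-variant enumeration.

    Sums over every causal-variant configuration on the natural scale (with a
    single global shift for stability): H1/H2 one causal variant in one
    trait, H3 two different causal variants, H4 the same causal variant.
    """
    p1, p2, p12 = priors
    m = len(beta_a)
    A = [log_abf(beta_a[k], se_a[k], W) for k in range(m)]
    B = [log_abf(beta_b[k], se_b[k], W) for k in range(m)]
    shift = max(max(A), max(B), 0.0)
    Ae = [math.exp(a - shift) for a in A]
    Be = [math.exp(b - shift) for b in B]
    s = math.exp(-shift)

    L1 = sum(Ae)
    L2 = sum(Be)
    L12 = sum(Ae[k] * Be[k] for k in range(m))
    Lcross = sum(Ae[j] * Be[k] for j in range(m) for k in range(m) if j != k)

    w = [
        s * s,                  # H0: no association in either trait
        p1 * L1 * s,            # H1
        p2 * L2 * s,            # H2
        p1 * p2 * Lcross,       # H3
        p12 * L12,              # H4
    ]
    tot = sum(w)
    return [x / tot for x in w]


def pearson_chi2_2x2(a, b, c, d):
    """Hand Pearson chi-squared for a 2x2 table [[a, b], [c, d]]."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den
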