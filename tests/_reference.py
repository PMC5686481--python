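"""Independent brute-force oracles used by the tests.

Deliberately naive: the ECDFs are materialised and evaluated explicitly at
every pooled sample value, unlike the streaming implementation under test.
"""

from typing import Sequence


def ks_brute_force(a: Sequence[float], b: Sequence[float]) -> float:
    """Max |ECDF_a(x) - ECDF_b(x)| over all pooled values x."""
    def ecdf(sample, x):
        return sum(1 for v in sample if v <= x) / len(sample)

    pooled = sorted(set(a) | set(b))
    return max(abs(ecdf(a, x) - ecdf(b, x)) for x in pooled)
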