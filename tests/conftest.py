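import mpmath as mp
import pytest

# the meditation example's unrounded sample correlation (cross-product sum
# over (n-1) s_X s_Y) and the rapid-resumption pairwise correlations
MEDITATION_R = -589.0 / 1629.0
MEDITATION_N = 54
FACEBOOK_R = 0.48
FACEBOOK_N = 40
RESUMPTION = dict(r_xy=0.51, r_xz=-0.78, r_yz=-0.66, n=40)


def jzs_bf_correlation_oracle(r: float, n: int, dps: int = 40) -> float:
    """High-precision brute-force evaluation of the JZS correlation integral.

    Adaptive quadrature at ``dps`` working digits over a split infinite
    domain, fully independent of the package's log-space substitution.
    """
    with mp.workdps(dps):
        r2 = mp.mpf(r) ** 2
        nn = mp.mpf(n)

        def f(g):
            return (
                (1 + g) ** ((nn - 2) / 2)
                * (1 + (1 - r2) * g) ** (-(nn - 1) / 2)
                * g ** mp.mpf("-1.5")
                * mp.e ** (-nn / (2 * g))
            )

        integral = mp.quad(f, [0, 1, 10, 100, 1000, mp.inf])
        return float(mp.sqrt(nn / (2 * mp.pi)) * integral)


def jzs_bf_partial_oracle(
    r0_sq: float, r1_sq: float, p0: int, p1: int, n: int, dps: int = 40
) -> float:
    """High-precision evaluation of the nested-model marginal ratio."""
    with mp.workdps(dps):
        nn = mp.mpf(n)

        def integral(r2, p):
            r2 = mp.mpf(r2)

            def f(g):
                return (
                    (1 + g) ** ((nn - 1 - p) / 2)
                    * (1 + (1 - r2) * g) ** (-(nn - 1) / 2)
                    * g ** mp.mpf("-1.5")
                    * mp.e ** (-nn / (2 * g))
                )

            return mp.quad(f, [0, 1, 10, 100, 1000, mp.inf])

        return float(integral(r1_sq, p1) / integral(r0_sq, p0))


@pytest.fixture(scope="session")
def bf_oracle():
    return jzs_bf_correlation_oracle


@pytest.fixture(scope="session")
def bf_partial_oracle():
    return jzs_bf_partial_oracle
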