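import numpy as np
import pytest

from glyqsp.pharmacology import HillParams, SynapseClassPD


@pytest.fixture(scope="session")
def pd_beneficial():
    """Lumped-class pharmacodynamics producing the inverse-U mechanism:
    NR2A/B (e-e) with higher EC50 and steeper Hill slope than NR2C/D (e-i)."""
    return SynapseClassPD(ee=HillParams(0.35, 1.84), ei=HillParams(0.25, 1.1))


@pytest.fixture(scope="session")
def pd_flat():
    """Identical e-e and e-i pharmacodynamics: the ratio is 1 everywhere."""
    return SynapseClassPD(ee=HillParams(0.3, 1.5), ei=HillParams(0.3, 1.5))


@pytest.fixture(scope="session")
def ratio_grid_oracle():
    """Brute-force dense-grid minimizer of the e-i/e-e Hill ratio."""

    def oracle(pd_, lo=1e-4, hi=1e4, n=100_000):
        g = np.logspace(np.log10(lo), np.log10(hi), n)

        def hill(x, p):
            r = (x / p.ec50) ** p.slope
            return r / (1 + r)

        num = pd_.gmax_ei * hill(g, pd_.ei)
        den = pd_.gmax_ee * hill(g, pd_.ee)
        if pd_.internalization_ei is not None:
            num = num * (1 - hill(g, pd_.internalization_ei))
        if pd_.internalization_ee is not None:
            den = den * (1 - hill(g, pd_.internalization_ee))
        ratio = num / den
        i = int(np.argmin(ratio))
        return g[i], ratio[i], (0 < i < n - 1)

    return oracle
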