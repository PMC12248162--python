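"""Hand-built fits and deterministic fit factories shared across test modules."""

from mavecal.distributions import SkewNormalParams
from mavecal.mixture import MixtureFit


def make_fit(wp=0.9, wb=0.05, wg=0.135, ws=0.02, theta_a=None, theta_n=None,
             score_range=(-7.0, 4.0)) -> MixtureFit:
    return MixtureFit(
        theta_abnormal=theta_a or SkewNormalParams(-3, 1, 0.2),
        theta_normal=theta_n or SkewNormalParams(0, 1, -0.2),
        weight_abnormal_per_sample={"P": wp, "B": wb, "G": wg, "S": ws},
        log_likelihood=0.0,
        converged=True,
        n_iterations=1,
        score_range=score_range,
    )


def fake_fit_factory(specs):
    """Bootstrap stand-in cycling through prescribed (w_P, w_B, w_G) triples."""
    calls = {"i": 0}

    def fake_fit(samples, n_restarts, tol, max_iter, seed):
        wp, wb, wg = specs[calls["i"] % len(specs)]
        calls["i"] += 1
        return make_fit(wp=wp, wb=wb, wg=wg, score_range=samples.score_range())

    return fake_fit
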