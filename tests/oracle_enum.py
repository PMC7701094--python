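"""Exhaustive-enumeration oracle for the genotype-probability HMM.

Sums over all (pairing configuration, chromatid path) combinations of
both parents on short marker chains; independent of the
forward-backward implementation it checks.
"""

import itertools

import numpy as np

from tetraqtl.hmm_probs import STATE_PAIR, _class_dosages, haldane_r


def _pairing_paths(c, T, rs):
    """All 4^T chromatid paths of one parent under pairing ``c``.

    Returns (probabilities (L,), transmitted-pair indices (L, T)).
    """
    states = np.array(list(itertools.product(range(4), repeat=T)))
    bits = np.stack([(states >> 1) & 1, states & 1], axis=2)  # (L, T, 2)
    prob = np.full(len(states), 0.25)
    for t in range(1, T):
        r = rs[t - 1]
        same = bits[:, t, :] == bits[:, t - 1, :]
        prob *= np.where(same, 1 - r, r).prod(axis=1)
    pairs = STATE_PAIR[4 * c + states]
    return prob, pairs


def enumerate_posteriors(pmap, lg, obs, eps):
    """Posterior (n, m, 36) over classes at the markers of one LG.

    ``obs`` is the (n, m) observed dosage matrix aligned to the LG's
    markers (NaN = missing).
    """
    positions = pmap.positions(lg)
    rs = haldane_r(np.diff(positions))
    ph1, ph2 = pmap.phases(lg)
    dose36 = _class_dosages(ph1, ph2)
    T = len(positions)
    n = obs.shape[0]

    # per-individual, per-marker emission over the 36 classes
    em = np.ones((n, T, 36))
    for t in range(T):
        o = obs[:, t]
        seen = ~np.isnan(o)
        em[seen, t, :] = np.where(
            o[seen, None] == dose36[None, t, :], 1 - eps, eps / 4
        )
    em6 = em.reshape(n, T, 6, 6)

    post = np.zeros((n, T, 36))
    for c1 in range(3):
        pr1, pairs1 = _pairing_paths(c1, T, rs)
        for c2 in range(3):
            pr2, pairs2 = _pairing_paths(c2, T, rs)
            base = (1 / 9) * np.outer(pr1, pr2)  # (L1, L2)
            for i in range(n):
                w = base.copy()
                for t in range(T):
                    w *= em6[i, t][np.ix_(pairs1[:, t], pairs2[:, t])]
                for t in range(T):
                    k = 6 * pairs1[:, t][:, None] + pairs2[:, t][None, :]
                    np.add.at(post[i, t], k.ravel(), w.ravel())
    return post / post.sum(axis=2, keepdims=True)
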