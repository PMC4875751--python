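"""The Jones-Taylor-Thornton (JTT) empirical amino-acid substitution model.

The model is a time-reversible continuous-time Markov chain on the 20
amino acids.  Its instantaneous rate matrix is Q_ij = s_ij * pi_j (i != j)
where ``s`` are the published JTT exchangeabilities and ``pi`` the JTT
equilibrium frequencies, normalised so that one unit of time corresponds to
one expected substitution per site.  Transition probabilities P(t) = exp(Qt)
are obtained from a symmetric eigendecomposition (exact for reversible Q),
which makes repeated evaluation at many branch lengths cheap.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: Amino-acid ordering used by the embedded JTT constants.
JTT_ORDER = "ARNDCQEGHILKMFPSTWYV"

# Lower-triangle exchangeabilities (row i=2..20, col j=1..i-1 in JTT_ORDER),
# as published in the original accepted-point-mutation counts scale.
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]

_JTT_FREQS = [
    0.076747923252076758, 0.051690948309051694, 0.042644957355042652,
    0.051543948456051550, 0.019802980197019805, 0.040751959248040752,
    0.061829938170061841, 0.073151926848073159, 0.022943977056022944,
    0.053760946239053767, 0.091903908096091905, 0.058675941324058678,
    0.023825976174023829, 0.040125959874040135, 0.050900949099050907,
    0.068764931235068771, 0.058564941435058568, 0.014260985739014262,
    0.032101967898032102, 0.066004933995066004,
]


class JTTModel:
    """JTT rate matrix with eigendecomposition-based P(t) evaluation."""

    def __init__(self) -> None:
        s = np.zeros((20, 20))
        k = 0
        for i in range(1, 20):
            for j in range(i):
                s[i, j] = s[j, i] = _JTT_LOWER[k]
                k += 1
        pi = np.asarray(_JTT_FREQS)
        pi = pi / pi.sum()
        Q = s * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # scale: expected rate sum_i pi_i * (-Q_ii) == 1 substitution/site/unit time
        rate = -np.dot(pi, np.diag(Q))
        Q /= rate
        self.pi = pi
        self.Q = Q
        # symmetric form B = D^{1/2} Q D^{-1/2}; eigh gives exact real spectrum
        d = np.sqrt(pi)
        B = Q * (d[:, None] / d[None, :])
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._w = w
        self._left = U / d[:, None]       # D^{-1/2} U
        self._right = (U * d[:, None]).T  # U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1 for t >= 0."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._left * np.exp(self._w * t)[None, :]) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def index(self, residue: str) -> int:
        i = JTT_ORDER.find(residue)
        if i < 0:
            raise ValueError(f"residue {residue!r} not in JTT alphabet")
        return i


@lru_cache(maxsize=1)
def default_model() -> JTTModel:
    return JTTModel()
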