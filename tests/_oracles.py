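"""Independent brute-force oracles used by the test suite.

Everything here is written definitionally (explicit loops, direct formulas,
fine-stepped numerical integration) and stays independent of the package's
implementation paths so it can serve as ground truth.
"""

from __future__ import annotations

import numpy as np

# --------------------------------------------------------------------------
# peak analysis: definitional local maxima, prominence, FWHM


def local_maxima(y) -> list[int]:
    """Strict local maxima by neighbour comparison (endpoints excluded)."""
    y = np.asarray(y, dtype=float)
    return [i for i in range(1, len(y) - 1) if y[i] > y[i - 1] and y[i] > y[i + 1]]


def prominence_and_bases(y, i) -> tuple[float, int, int]:
    """Topographic prominence of peak i with its left/right base indices."""
    y = np.asarray(y, dtype=float)
    left_min, left_base = y[i], i
    j = i - 1
    while j >= 0 and y[j] <= y[i]:
        if y[j] < left_min:
            left_min, left_base = y[j], j
        j -= 1
    right_min, right_base = y[i], i
    j = i + 1
    while j < len(y) and y[j] <= y[i]:
        if y[j] < right_min:
            right_min, right_base = y[j], j
        j += 1
    return y[i] - max(left_min, right_min), left_base, right_base


def fwhm(y, i) -> float:
    """Width at half the prominence-referenced height, linear interpolation,
    clipped at the peak's bases."""
    y = np.asarray(y, dtype=float)
    prom, lb, rb = prominence_and_bases(y, i)
    h = y[i] - 0.5 * prom
    k = i
    while k > lb and y[k] > h:
        k -= 1
    left_ip = float(k)
    if y[k] < h:
        left_ip = k + (h - y[k]) / (y[k + 1] - y[k])
    k = i
    while k < rb and y[k] > h:
        k += 1
    right_ip = float(k)
    if y[k] < h:
        right_ip = k - (h - y[k]) / (y[k - 1] - y[k])
    return right_ip - left_ip


def peak_table(x, polarity: str, min_prominence: float):
    """(locations, signed amplitudes, fwhms) for one polarity, brute force."""
    x = np.asarray(x, dtype=float)
    y = x if polarity == "positive" else -x
    locs, amps, widths = [], [], []
    for i in local_maxima(y):
        prom, _, _ = prominence_and_bases(y, i)
        if prom >= min_prominence and y[i] > 0:
            locs.append(i)
            amps.append(x[i])
            widths.append(fwhm(y, i))
    return np.array(locs), np.array(amps), np.array(widths)


# --------------------------------------------------------------------------
# the 30 features, direct formulas


def _mean(v):
    return float(np.mean(v)) if len(v) else 0.0


def _sep(locs):
    return float(np.mean(np.diff(locs))) if len(locs) >= 2 else 0.0


def oracle_autocorr(x) -> np.ndarray:
    """O(n^2) definitional lag sums, normalised to lag 0."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = np.array([sum(x[i] * x[i + k] for i in range(n - k)) for k in range(n)])
    return r / r[0]


def _hann_periodic(n):
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n) / n)


def oracle_welch(x, fs, nperseg=30) -> np.ndarray:
    """Welch PSD: Hann window, 50% overlap, density scaling, one-sided."""
    x = np.asarray(x, dtype=float)
    nperseg = min(nperseg, len(x))
    step = nperseg - nperseg // 2
    win = _hann_periodic(nperseg)
    u = fs * float(np.sum(win**2))
    segs = []
    start = 0
    while start + nperseg <= len(x):
        seg = x[start : start + nperseg] * win
        p = np.abs(np.fft.rfft(seg)) ** 2 / u
        p[1:] *= 2.0
        if nperseg % 2 == 0:
            p[-1] /= 2.0
        segs.append(p)
        start += step
    return np.mean(segs, axis=0)


def oracle_periodogram(x, fs) -> np.ndarray:
    """Rectangular-window full-length periodogram, density scaling, one-sided."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    p = np.abs(np.fft.rfft(x)) ** 2 / (fs * n)
    p[1:] *= 2.0
    if n % 2 == 0:
        p[-1] /= 2.0
    return p


def oracle_features(x, fs=30.0) -> np.ndarray:
    """All 30 descriptors from their printed definitions."""
    x = np.asarray(x, dtype=float)
    dt = 1.0 / fs
    mp = 0.05 * np.max(np.abs(x)) if np.any(x) else 0.0
    ploc, pamp, pw = peak_table(x, "positive", mp)
    nloc, namp, nw = peak_table(x, "negative", mp)

    f = np.zeros(30)
    if len(pamp):
        i = int(np.argmax(pamp))
        f[0], f[1] = pamp[i], ploc[i]
    if len(namp):
        i = int(np.argmin(namp))
        f[2], f[3] = namp[i], nloc[i]
    f[4] = np.mean((x - np.mean(x)) ** 2)
    f[5] = np.sqrt(np.mean(x**2))
    f[6], f[7] = len(ploc), len(nloc)
    f[8], f[9] = _mean(pamp), _mean(namp)
    f[10], f[11] = _mean(pw), _mean(nw)
    f[12], f[13] = _sep(ploc), _sep(nloc)
    f[14] = sum(1 for i in range(len(x) - 1) if x[i] * x[i + 1] < 0)
    f[15] = np.sum(x) * dt
    f[16] = np.sum(np.abs(x)) * dt
    pos_area = np.sum(x[x > 0]) * dt
    neg_area = -np.sum(x[x < 0]) * dt
    if f[16] > 0:
        f[17] = 100.0 * pos_area / f[16]
        f[18] = 100.0 * neg_area / f[16]

    if np.any(x):
        r = oracle_autocorr(x)
        rloc, ramp, rw = peak_table(r, "positive", 0.05 * np.max(np.abs(r)))
        f[19] = np.mean(r)
        f[20] = len(rloc)
        f[21], f[22], f[23] = _mean(ramp), _mean(rw), _sep(rloc)

        f[24] = np.mean(oracle_welch(x, fs))
        pg = oracle_periodogram(x, fs)
        gloc, gamp, gw = peak_table(pg, "positive", 0.05 * np.max(np.abs(pg)))
        f[25] = np.mean(pg)
        f[26] = len(gloc)
        f[27], f[28], f[29] = _mean(gamp), _mean(gw), _sep(gloc)
    return f


# --------------------------------------------------------------------------
# propagation delay: fine-stepped line integral of slowness

C_MM_PER_NS = 299.792458


def oracle_leg_delay(a, p, media, n_steps=200_000) -> float:
    """Midpoint line integral of per-medium slowness along the straight ray."""
    a = np.asarray(a, dtype=float)
    p = np.asarray(p, dtype=float)
    centre = np.asarray(media.breast_centre, dtype=float)
    length = np.hypot(*(p - a))
    ts = (np.arange(n_steps) + 0.5) / n_steps
    pts = a[None, :] + ts[:, None] * (p - a)[None, :]
    r = np.hypot(pts[:, 0] - centre[0], pts[:, 1] - centre[1])
    eps = np.where(
        r > media.breast_radius,
        media.eps_immersion,
        np.where(r > media.interior_radius, media.eps_skin, media.eps_interior),
    )
    return float(np.sum(np.sqrt(eps)) * (length / n_steps) / C_MM_PER_NS)


def oracle_roundtrip(tumour_position, channel, array, media) -> float:
    tx = array.positions[channel.tx]
    rx = array.positions[channel.rx]
    return oracle_leg_delay(tx, tumour_position, media) + oracle_leg_delay(
        rx, tumour_position, media
    )


# --------------------------------------------------------------------------
# AUC via the Mann–Whitney pairwise identity


def oracle_auc(scores, labels, positive="malignant") -> float:
    """P(score_pos > score_neg) + 0.5 P(tie), by explicit pairwise counting."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    pos, neg = scores[y], scores[~y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))


# --------------------------------------------------------------------------
# ideal sinc (frequency-domain brick-wall) decimation


def oracle_sinc_decimate(x, q) -> np.ndarray:
    """Zero all frequencies above the output Nyquist, keep every q-th sample."""
    x = np.asarray(x, dtype=float)
    spec = np.fft.rfft(x)
    cut = len(x) // (2 * q)
    spec[cut + 1 :] = 0.0
    return np.fft.irfft(spec, n=len(x))[::q]
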