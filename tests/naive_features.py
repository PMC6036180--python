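"""Independent, loop-based reference implementations of every per-epoch
feature, written directly from the feature definitions (no vectorization,
no code shared with the package's feature paths)."""

from __future__ import annotations

import numpy as np


# -- envelope ---------------------------------------------------------------

def naive_envelope(x):
    """|x + jH{x}|^2 via an explicit FFT construction of the analytic signal."""
    n = len(x)
    X = np.fft.fft(x)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1:n // 2] = 2.0
    else:
        h[1:(n + 1) // 2] = 2.0
    analytic = np.fft.ifft(X * h)
    return np.abs(analytic) ** 2


# -- amplitude --------------------------------------------------------------

def naive_amplitude(x):
    x = np.asarray(x, float)
    n = len(x)
    mu = sum(x) / n
    m2 = sum((v - mu) ** 2 for v in x) / n
    m3 = sum((v - mu) ** 3 for v in x) / n
    m4 = sum((v - mu) ** 4 for v in x) / n
    env = naive_envelope(x)
    emu = env.mean()
    return {
        "total_power": float(sum(v * v for v in x) / n),
        "sd": float(np.sqrt(m2 * n / (n - 1))),
        "skewness": float(m3 / m2 ** 1.5) if m2 > 0 else 0.0,
        "kurtosis": float(m4 / m2 ** 2) if m2 > 0 else 0.0,
        "envelope_mean": float(emu),
        "envelope_sd": float(np.sqrt(sum((e - emu) ** 2 for e in env)
                                     / (len(env) - 1))),
    }


# -- rEEG -------------------------------------------------------------------

def naive_reeg(x, fs, win=2.0, overlap=0.5):
    wlen = int(round(win * fs))
    step = int(round(wlen * (1 - overlap)))
    ranges = []
    s = 0
    while s + wlen <= len(x):
        seg = x[s:s + wlen]
        ranges.append(max(seg) - min(seg))
        s += step
    r = np.asarray(ranges, float)
    mean, med = r.mean(), np.median(r)
    p5, p95 = np.percentile(r, 5), np.percentile(r, 95)
    sd = r.std(ddof=1)
    cv = sd / mean if mean != 0 else 0.0
    sym = (((p95 - med) - (med - p5)) / (p95 - p5)) if p95 > p5 else 0.0
    return {"mean": mean, "median": med, "p5": p5, "p95": p95, "sd": sd,
            "cv": cv, "symmetry": sym}


# -- spectra ----------------------------------------------------------------

def _hamming_periodic(n):
    k = np.arange(n)
    return 0.54 - 0.46 * np.cos(2 * np.pi * k / n)


def naive_segment_spectra(x, fs, win=2.0, overlap=0.5):
    """One-sided density-scaled short-time periodograms, segment by segment."""
    wlen = int(round(win * fs))
    step = int(round(wlen * (1 - overlap)))
    w = _hamming_periodic(wlen)
    freqs = np.fft.rfftfreq(wlen, 1.0 / fs)
    segs = []
    s = 0
    while s + wlen <= len(x):
        seg = np.asarray(x[s:s + wlen], float)
        seg = seg - seg.mean()
        spec = np.fft.rfft(seg * w)
        p = (np.abs(spec) ** 2) / (fs * np.sum(w ** 2))
        p[1:] *= 2.0
        if wlen % 2 == 0:
            p[-1] /= 2.0
        segs.append(p)
        s += step
    return freqs, np.array(segs)


def naive_welch(x, fs, win=2.0, overlap=0.5):
    freqs, S = naive_segment_spectra(x, fs, win, overlap)
    return freqs, S.mean(axis=0)


def naive_spectral(x, fs, lo, hi, total_lo=0.5, total_hi=30.0,
                   win=2.0, overlap=0.5, edge_fraction=0.95):
    freqs, S = naive_segment_spectra(x, fs, win, overlap)
    psd = S.mean(axis=0)
    df = freqs[1] - freqs[0]
    inband = [k for k in range(len(freqs)) if lo <= freqs[k] < hi]
    intotal = [k for k in range(len(freqs)) if total_lo <= freqs[k] < total_hi]
    p = psd[inband]
    power = sum(p) * df
    total = sum(psd[k] for k in intotal) * df
    rel = power / total if total > 0 else 0.0
    if sum(p) > 0:
        if all(v > 0 for v in p):
            geo = np.exp(np.mean([np.log(v) for v in p]))
            wiener = geo / np.mean(p)
        else:
            wiener = 0.0
        q = p / sum(p)
        ent = -sum(v * np.log(v) for v in q if v > 0)
        shannon = ent / np.log(len(p))
        csum, edge = 0.0, freqs[inband[-1]]
        target = edge_fraction * sum(p)
        for k, v in zip(inband, p):
            csum += v
            if csum >= target - 1e-12 * abs(target):
                edge = freqs[k]
                break
    else:
        wiener, shannon, edge = 0.0, 0.0, lo
    amp = np.sqrt(S[:, inband])
    diffs = [(amp[t + 1] - amp[t]) ** 2 for t in range(len(amp) - 1)]
    sdiff = float(np.mean(diffs))
    return {"power": power, "relative_power": rel, "wiener_entropy": wiener,
            "shannon_entropy": shannon, "edge_freq": edge,
            "spectral_diff": sdiff}


# -- connectivity -----------------------------------------------------------

def naive_bsi(psds_left, psds_right, freqs, lo, hi):
    L = np.mean(psds_left, axis=0)
    R = np.mean(psds_right, axis=0)
    vals = []
    for k in range(len(freqs)):
        if lo <= freqs[k] < hi and (L[k] + R[k]) > 0:
            vals.append(abs((L[k] - R[k]) / (L[k] + R[k])))
    return float(np.mean(vals)) if vals else 0.0


def naive_rank(v):
    """Average-tie ranks, 1-based."""
    v = np.asarray(v)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v), float)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def naive_env_xcorr(env_pairs_left, env_pairs_right, fs, max_lag=0.2):
    """Rank each whole envelope once; Pearson of lag-shifted rank slices.

    Lag l correlates left[t+l] with right[t]; ties in the maximum resolve
    to the most negative lag (first occurrence scanning lags in order).
    """
    L = int(round(max_lag * fs))
    maxima, arglags = [], []
    for el, er in zip(env_pairs_left, env_pairs_right):
        if max(el) == min(el) or max(er) == min(er):
            continue
        rl, rr = naive_rank(el), naive_rank(er)
        best_r, best_lag = -np.inf, None
        for lag in range(-L, L + 1):
            if lag >= 0:
                a, b = rl[lag:], rr[:len(rr) - lag]
            else:
                a, b = rl[:len(rl) + lag], rr[-lag:]
            r = np.corrcoef(a, b)[0, 1]
            if r > best_r:
                best_r, best_lag = r, lag
        maxima.append(best_r)
        arglags.append(best_lag / fs)
    return {"env_xcorr_max": float(np.median(maxima)),
            "env_xcorr_lag": float(np.median(arglags))}


def naive_coherence(x, y, fs, win=2.0, overlap=0.5):
    """Magnitude-squared coherence from segment cross-spectra."""
    wlen = int(round(win * fs))
    step = int(round(wlen * (1 - overlap)))
    w = _hamming_periodic(wlen)
    freqs = np.fft.rfftfreq(wlen, 1.0 / fs)
    Pxx = np.zeros(len(freqs))
    Pyy = np.zeros(len(freqs))
    Pxy = np.zeros(len(freqs), complex)
    count, s = 0, 0
    while s + wlen <= len(x):
        a = np.asarray(x[s:s + wlen], float)
        b = np.asarray(y[s:s + wlen], float)
        A = np.fft.rfft((a - a.mean()) * w)
        B = np.fft.rfft((b - b.mean()) * w)
        Pxx += np.abs(A) ** 2
        Pyy += np.abs(B) ** 2
        Pxy += A * np.conj(B)
        count += 1
        s += step
    Pxx, Pyy, Pxy = Pxx / count, Pyy / count, Pxy / count
    with np.errstate(invalid="ignore", divide="ignore"):
        cxy = np.abs(Pxy) ** 2 / (Pxx * Pyy)
    return freqs, np.nan_to_num(cxy)


def naive_coherence_features(xs_left, xs_right, fs, lo, hi,
                             win=2.0, overlap=0.5):
    means, fmaxes = [], []
    for x, y in zip(xs_left, xs_right):
        freqs, cxy = naive_coherence(x, y, fs, win, overlap)
        inband = [k for k in range(len(freqs)) if lo <= freqs[k] < hi]
        vals = cxy[inband]
        means.append(np.mean(vals))
        fmaxes.append(freqs[inband[int(np.argmax(vals))]])
    return {"coherence_mean": float(np.mean(means)),
            "coherence_max_freq": float(np.median(fmaxes))}


# -- fractal dimension ------------------------------------------------------

def naive_higuchi(x, kmax=6):
    x = np.asarray(x, float)
    n = len(x)
    ks, Ls = [], []
    for k in range(1, kmax + 1):
        Lm_sum = 0.0
        for m in range(k):
            idx = list(range(m, n, k))
            dist = sum(abs(x[idx[i]] - x[idx[i - 1]]) for i in range(1, len(idx)))
            nseg = len(idx) - 1
            Lm_sum += dist * (n - 1) / (nseg * k) / k
        Lk = Lm_sum / k
        ks.append(np.log(1.0 / k))
        Ls.append(np.log(Lk))
    slope = np.polyfit(ks, Ls, 1)[0]
    return float(min(max(slope, 1.0), 2.0))
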