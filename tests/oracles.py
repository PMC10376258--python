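"""Independent brute-force oracles for closed-form feature definitions.

Every oracle is a plain-Python direct-summation implementation, written
against the feature definition rather than against the package code, so the
vectorized extractors can be checked for exact agreement.
"""

import math

import numpy as np


def _rms(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def o_mean(x):
    return sum(x) / len(x)


def o_mav(x):
    return sum(abs(v) for v in x) / len(x)


def o_iemg(x):
    return sum(abs(v) for v in x)


def o_rms(x):
    return _rms(x)


def o_var(x):
    return sum(v * v for v in x) / (len(x) - 1)


def o_ssi(x):
    return sum(v * v for v in x)


def o_msr(x):
    return sum(math.sqrt(abs(v)) for v in x) / len(x)


def o_rsm0(x):
    return math.sqrt(sum(v * v for v in x))


def o_rsd1(x):
    return math.sqrt(sum((x[i + 1] - x[i]) ** 2 for i in range(len(x) - 1)))


def o_rsd2(x):
    dd = [x[i + 2] - 2 * x[i + 1] + x[i] for i in range(len(x) - 2)]
    return math.sqrt(sum(v * v for v in dd))


def o_asm(x):
    dd = [x[i + 2] - 2 * x[i + 1] + x[i] for i in range(len(x) - 2)]
    return sum(abs(v) for v in dd) / len(dd)


def o_rog(x):
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    return _rms(d) / (_rms(x) + 1e-12)


def o_nsv(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1) if x[i + 1] < x[i])


def o_er(x):
    half = len(x) // 2
    return sum(v * v for v in x[:half]) / (sum(v * v for v in x) + 1e-12)


def o_mavs(x):
    half = len(x) // 2
    first = sum(abs(v) for v in x[:half]) / half
    second = sum(abs(v) for v in x[half:]) / (len(x) - half)
    return second - first


def o_tm3(x):
    return abs(sum(v ** 3 for v in x) / len(x))


def o_tm4(x):
    return sum(v ** 4 for v in x) / len(x)


def o_tm5(x):
    return abs(sum(v ** 5 for v in x) / len(x))


def o_v3(x):
    return (sum(abs(v) ** 3 for v in x) / len(x)) ** (1 / 3)


def o_v4(x):
    return (sum(abs(v) ** 4 for v in x) / len(x)) ** 0.25


def o_wl(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))


def o_aac(x):
    return o_wl(x) / (len(x) - 1)


def o_dasdv(x):
    return math.sqrt(sum((x[i + 1] - x[i]) ** 2 for i in range(len(x) - 1)) / (len(x) - 1))


def o_dvarv(x):
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    return sum(v * v for v in d) / (len(d) - 1)


def o_zc(x, threshold):
    count = 0
    for i in range(len(x) - 1):
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) > threshold:
            count += 1
    return float(count)


def o_ssc(x, threshold):
    count = 0
    for i in range(1, len(x) - 1):
        if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) > threshold:
            count += 1
    return float(count)


def o_wamp(x, threshold):
    return float(sum(1 for i in range(len(x) - 1) if abs(x[i + 1] - x[i]) > threshold))


def o_myop(x, threshold):
    return sum(1 for v in x if abs(v) > threshold) / len(x)


def o_mmav1(x):
    n = len(x)
    total = 0.0
    for i, v in enumerate(x):
        w = 1.0 if 0.25 * n <= i <= 0.75 * n else 0.5
        total += w * abs(v)
    return total / n


def o_mmav2(x):
    n = len(x)
    total = 0.0
    for i, v in enumerate(x):
        if i < 0.25 * n:
            w = 4.0 * i / n
        elif i > 0.75 * n:
            w = 4.0 * (n - i) / n
        else:
            w = 1.0
        total += w * abs(v)
    return total / n


def o_mmav5(x):
    n = len(x)
    weights = [0.5, 0.75, 1.0, 0.75, 0.5]
    total = 0.0
    for i, v in enumerate(x):
        q = min((i * 5) // n, 4)
        total += weights[q] * abs(v)
    return total / n


def o_meda(x):
    return float(np.median([abs(v) for v in x]))


def o_maxa(x):
    return max(abs(v) for v in x)


def o_mtkeo(x):
    psi = [x[i] ** 2 - x[i - 1] * x[i + 1] for i in range(1, len(x) - 1)]
    return sum(psi) / len(psi)


def o_ewl(x):
    total = 0.0
    n = len(x) - 1
    for i in range(n):
        p = 0.75 if n // 4 <= i < (3 * n) // 4 else 0.5
        total += abs(x[i + 1] - x[i]) ** p
    return total


def o_higuchi(x, kmax):
    """Direct-loop Higuchi curve-length slope."""
    n = len(x)
    logs = []
    for k in range(1, kmax + 1):
        lks = []
        for m in range(k):
            idx = list(range(m, n, k))
            if len(idx) < 2:
                continue
            dist = sum(abs(x[idx[j + 1]] - x[idx[j]]) for j in range(len(idx) - 1))
            lks.append(dist * (n - 1) / (k * (len(idx) - 1)) / k)
        logs.append((math.log(1.0 / k), math.log(sum(lks) / len(lks) + 1e-30)))
    xs = [a for a, _ in logs]
    ys = [b for _, b in logs]
    xbar, ybar = sum(xs) / len(xs), sum(ys) / len(ys)
    num = sum((a - xbar) * (b - ybar) for a, b in logs)
    den = sum((a - xbar) ** 2 for a in xs)
    return num / den


#: name -> (oracle, needs_threshold) for the closed-form features.
CLOSED_FORM = {
    "MEAN": o_mean, "MAV": o_mav, "IEMG": o_iemg, "RMS": o_rms, "VAR": o_var,
    "SSI": o_ssi, "MSR": o_msr, "RSM0": o_rsm0, "RSD1": o_rsd1, "RSD2": o_rsd2,
    "ASM": o_asm, "ROG": o_rog, "NSV": o_nsv, "ER": o_er, "MAVS": o_mavs,
    "TM3": o_tm3, "TM4": o_tm4, "TM5": o_tm5, "V3": o_v3, "V4": o_v4,
    "WL": o_wl, "AAC": o_aac, "DASDV": o_dasdv, "DVARV": o_dvarv, "EWL": o_ewl,
    "MMAV1": o_mmav1, "MMAV2": o_mmav2, "MMAV5": o_mmav5,
    "MEDA": o_meda, "MAXA": o_maxa, "MTKEO": o_mtkeo,
}

THRESHOLDED = {"ZC": o_zc, "SSC": o_ssc, "WAMP": o_wamp, "MYOP": o_myop}
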