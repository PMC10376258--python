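"""Spatial (SD) cross-channel ratio features.

These compare aggregate activity between muscle groups identified by the
channel role tags (flexor, extensor, thenar), e.g. the flexor/extensor power
ratio.  Denominators are epsilon-guarded so the ratios stay finite even when
one muscle group is silent.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError

_TINY = 1e-300


def _group_indices(roles, role):
    idx = [i for i, r in enumerate(roles) if r == role]
    if not idx:
        raise ConfigurationError(f"no channel tagged {role!r} among roles {roles}")
    return idx


def _ratio(num: float, den: float) -> float:
    # relative guard: caps the ratio near 1e12 when the denominator vanishes
    return float(num / (den + 1e-12 * num + _TINY))


def group_power(window, roles, role):
    idx = _group_indices(roles, role)
    return float(np.mean(window[:, idx] ** 2))


def group_mav(window, roles, role):
    idx = _group_indices(roles, role)
    return float(np.mean(np.abs(window[:, idx])))


def power_ratio(window, roles, num_role, den_role):
    return _ratio(group_power(window, roles, num_role),
                  group_power(window, roles, den_role))


def mav_ratio(window, roles, num_role, den_role):
    return _ratio(group_mav(window, roles, num_role),
                  group_mav(window, roles, den_role))
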