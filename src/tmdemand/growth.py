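"""LMS growth-reference transforms, weight imputation, and forward weight projection.

The LMS method (Box-Cox power L, median M, coefficient of variation S)
skew-normalizes an anthropometric measurement X at a given sex and age:

    z = ((X/M)**L - 1) / (L*S)   for L != 0
    z = ln(X/M) / S              for L == 0

Weight trajectories are projected forward under the constant-z assumption:
a patient's z-score against the reference is held fixed, and body growth is
treated as negligible from age 20 onward.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Age (years) after which body growth is treated as negligible.
ADULT_AGE_YEARS = 20.0

#: |L| below this uses the logarithmic (L -> 0) branch of the LMS transform.
_L_LOG_TOL = 1e-7


class LMSCoverageError(ValueError):
    """The LMS reference has no entries for the requested sex or age."""


def _normalize_sex(values) -> np.ndarray:
    """Map CDC-style sex codes (1/2) and letter codes to 'M'/'F'."""
    mapping = {
        "1": "M", "m": "M", "male": "M",
        "2": "F", "f": "F", "female": "F",
    }
    arr = np.atleast_1d(np.asarray(values, dtype=object))
    out = np.empty(arr.shape, dtype=object)
    for i, v in enumerate(arr.ravel()):
        key = str(v).strip().lower()
        if key.endswith(".0"):  # float-coded CDC files
            key = key[:-2]
        if key not in mapping:
            raise ValueError(f"unrecognized sex code: {v!r}")
        out.ravel()[i] = mapping[key]
    return out


@dataclass
class LMSReference:
    """Sex- and age-indexed (L, M, S) triples with linear age interpolation.

    ``table`` columns: ``sex`` ('M'/'F'), ``agemos`` (age in months, strictly
    increasing within sex), ``L``, ``M`` (median kg, > 0), ``S`` (> 0).
    Accepts the CDC weight-for-age (``wtage``) column dialect on read.
    """

    table: pd.DataFrame
    _by_sex: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        required = {"sex", "agemos", "L", "M", "S"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"LMS table missing columns: {sorted(missing)}")
        t = t.copy()
        t["sex"] = _normalize_sex(t["sex"].to_numpy())
        if (t["M"] <= 0).any() or (t["S"] <= 0).any():
            raise ValueError("LMS table requires M > 0 and S > 0 everywhere")
        for sex, sub in t.groupby("sex"):
            sub = sub.sort_values("agemos")
            ages = sub["agemos"].to_numpy(dtype=float)
            if np.any(np.diff(ages) <= 0):
                raise ValueError(f"duplicate/non-increasing agemos for sex {sex}")
            self._by_sex[sex] = {
                "agemos": ages,
                "L": sub["L"].to_numpy(dtype=float),
                "M": sub["M"].to_numpy(dtype=float),
                "S": sub["S"].to_numpy(dtype=float),
            }
        self.table = t.sort_values(["sex", "agemos"]).reset_index(drop=True)

    @classmethod
    def read_csv(cls, path) -> "LMSReference":
        """Read an LMS CSV; column names are matched case-insensitively.

        Real CDC ``wtage`` files (columns Sex, Agemos, L, M, S, plus
        percentile columns, sex coded 1=male/2=female) load unchanged.
        """
        raw = pd.read_csv(path, comment="#")
        cols = {c.lower(): c for c in raw.columns}
        try:
            sub = raw[[cols["sex"], cols["agemos"], cols["l"], cols["m"], cols["s"]]]
        except KeyError as exc:
            raise ValueError(f"not an LMS table: missing column {exc}") from exc
        sub.columns = ["sex", "agemos", "L", "M", "S"]
        return cls(sub)

    def to_csv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, index=False)

    def sexes(self) -> list[str]:
        return sorted(self._by_sex)

    def age_range(self, sex: str) -> tuple[float, float]:
        sex = _normalize_sex(sex)[0]
        if sex not in self._by_sex:
            raise LMSCoverageError(f"no LMS entries for sex {sex!r}")
        ages = self._by_sex[sex]["agemos"]
        return float(ages[0]), float(ages[-1])

    def params(self, sex, age_months):
        """Interpolated (L, M, S) at ``age_months`` for one sex.

        Ages beyond the tabulated range clamp to the nearest entry with a
        warning (the standard references end at 240 months).
        """
        sex = _normalize_sex(sex)[0]
        if sex not in self._by_sex:
            raise LMSCoverageError(
                f"no LMS entries for sex {sex!r} (have {self.sexes()})"
            )
        d = self._by_sex[sex]
        age = np.asarray(age_months, dtype=float)
        lo, hi = d["agemos"][0], d["agemos"][-1]
        if np.any(age < lo) or np.any(age > hi):
            warnings.warn(
                f"age(s) outside LMS range [{lo}, {hi}] months for sex {sex}; "
                "clamping to nearest tabulated entry",
                stacklevel=2,
            )
        L = np.interp(age, d["agemos"], d["L"])
        M = np.interp(age, d["agemos"], d["M"])
        S = np.interp(age, d["agemos"], d["S"])
        return L, M, S


def lms_z(weight, L, M, S):
    """z-score of ``weight`` (kg) under LMS parameters; vectorized."""
    weight = np.asarray(weight, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(weight <= 0):
        raise ValueError("weight must be positive")
    ratio = weight / M
    with np.errstate(divide="ignore", invalid="ignore"):
        power = (np.power(ratio, L) - 1.0) / (L * S)
        logb = np.log(ratio) / S
    z = np.where(np.abs(L) < _L_LOG_TOL, logb, power)
    return z.item() if z.ndim == 0 else z


def lms_inverse(z, L, M, S):
    """Weight (kg) at z-score ``z``; exact algebraic inverse of :func:`lms_z`."""
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    base = 1.0 + L * S * z
    use_log = np.abs(L) < _L_LOG_TOL
    if np.any(~use_log & (base <= 0)):
        raise ValueError("z outside LMS support: 1 + L*S*z must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        power = M * np.power(np.where(use_log, 1.0, base), 1.0 / np.where(use_log, 1.0, L))
        logb = M * np.exp(S * z)
    w = np.where(use_log, logb, power)
    return w.item() if w.ndim == 0 else w


def zscore_at_age(weight, sex, age_years, lms: LMSReference):
    """z-score of an observed weight, evaluated at min(age, 20) years."""
    age_mo = np.minimum(np.asarray(age_years, dtype=float), ADULT_AGE_YEARS) * 12.0
    L, M, S = lms.params(sex, age_mo)
    return lms_z(weight, L, M, S)


def project_weight(current_weight, sex, current_age, target_age, lms: LMSReference):
    """Project a weight forward holding the z-score constant.

    Growth is negligible from age 20: observed adult weights carry forward
    unchanged, and projections for younger patients cap at the age-20
    reference.
    """
    if target_age < current_age:
        raise ValueError("target_age must be >= current_age")
    if current_age >= ADULT_AGE_YEARS:
        return float(current_weight)
    z0 = zscore_at_age(current_weight, sex, current_age, lms)
    eval_age = min(float(target_age), ADULT_AGE_YEARS)
    L, M, S = lms.params(sex, eval_age * 12.0)
    return float(lms_inverse(z0, L, M, S))


def impute_weight(sex, age, peer_zscores, lms: LMSReference):
    """Expected weight at the mean z-score of same-age-group peers."""
    peers = np.asarray(peer_zscores, dtype=float)
    if peers.size == 0:
        raise ValueError(
            "no peer z-scores in this age group; fall back to the nearest "
            "non-empty group (see age_group_mean_z)"
        )
    zbar = float(peers.mean())
    eval_age = min(float(age), ADULT_AGE_YEARS)
    L, M, S = lms.params(sex, eval_age * 12.0)
    return float(lms_inverse(zbar, L, M, S))


def age_group_mean_z(zscores, ages, target_age) -> float:
    """Mean z in the target age bin; falls back to the nearest non-empty bin.

    Bins are 1-year bins below 20 and a single adult bin (20+).
    """
    zscores = np.asarray(zscores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    ok = np.isfinite(zscores)
    zscores, ages = zscores[ok], ages[ok]
    if zscores.size == 0:
        raise ValueError("no peer z-scores available in any age group")

    def bin_of(a):
        return int(min(np.floor(a), ADULT_AGE_YEARS))

    bins = np.array([bin_of(a) for a in ages])
    target_bin = bin_of(target_age)
    in_bin = bins == target_bin
    if not in_bin.any():
        nearest = bins[np.argmin(np.abs(bins - target_bin))]
        in_bin = bins == nearest
    return float(zscores[in_bin].mean())


def backfill_weights(panel: pd.DataFrame, lms: LMSReference):
    """Fill missing ``weight_kg`` by carrying each patient's nearest observed
    z-score to the missing ages (constant-z rule).

    Patients with no observed weight at all cannot be backfilled and are
    dropped; their ids are returned in the exclusion list.

    Returns ``(panel, excluded_ids)``; ``panel`` has a fully populated
    ``weight_kg`` column (copy; input untouched).
    """
    panel = panel.copy()
    excluded: list = []
    out_weight = panel["weight_kg"].to_numpy(dtype=float).copy()
    keep = np.ones(len(panel), dtype=bool)
    for pid, idx in panel.groupby("patient_id", sort=False).indices.items():
        idx = np.asarray(idx)
        w = panel["weight_kg"].to_numpy(dtype=float)[idx]
        ages = panel["age_years"].to_numpy(dtype=float)[idx]
        sex = panel["sex"].to_numpy()[idx][0]
        obs = np.isfinite(w) & (w > 0)
        if not obs.any():
            excluded.append(pid)
            keep[idx] = False
            continue
        if obs.all():
            continue
        obs_ages = ages[obs]
        obs_z = np.atleast_1d(zscore_at_age(w[obs], sex, obs_ages, lms))
        for j in np.where(~obs)[0]:
            near = np.argmin(np.abs(obs_ages - ages[j]))
            eval_age = min(ages[j], ADULT_AGE_YEARS)
            L, M, S = lms.params(sex, eval_age * 12.0)
            out_weight[idx[j]] = lms_inverse(obs_z[near], L, M, S)
    panel["weight_kg"] = out_weight
    return panel.loc[keep].reset_index(drop=True), excluded
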