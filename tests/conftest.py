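import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from quadarray.io import ArrayTable
from quadarray.simulate import GeneratorParams, generate_dataset

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_features(rows):
    """Build a canonical feature frame from
    (probe, rep, gps, manual, soft, cv, control) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "replicate_index",
            "gps",
            "manual_flag",
            "outlier_flag",
            "pixel_cv",
            "is_control",
        ],
    ).astype(
        {
            "probe_id": str,
            "replicate_index": int,
            "gps": float,
            "manual_flag": bool,
            "outlier_flag": bool,
            "pixel_cv": float,
            "is_control": bool,
        }
    )


def make_table(rows, sample_id="S1", subset="iNKT1", strain="BALBC", experiment="Exp1"):
    return ArrayTable(
        sample_id=sample_id,
        strain=strain,
        subset=subset,
        experiment_id=experiment,
        features=make_features(rows),
    )


def clean_quad(probe, values, cv=0.1):
    return [(probe, i + 1, v, False, False, cv, False) for i, v in enumerate(values)]


# ---------------------------------------------------------------- oracles


def quantile_oracle(values, q):
    """Type-7 quantile by explicit order statistics and interpolation,
    independent of numpy.percentile."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    h = (n - 1) * (q / 100.0)
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def fence_oracle(members, k=1.42, cv_max=0.5, convention="quartile_fences"):
    """Brute-force re-application of exclusion rules (i)-(iv) to a
    quadruplicate of (value, manual, soft, cv) tuples.  Returns the reason
    list ('' = surviving), written independently of the implementation."""
    reasons = []
    for v, man, soft, cv in members:
        if man:
            reasons.append("manual_flag")
        elif soft:
            reasons.append("software_outlier")
        else:
            reasons.append("")
    pool = [m[0] for m, r in zip(members, reasons) if r == ""]
    if pool:
        q1 = quantile_oracle(pool, 25)
        q3 = quantile_oracle(pool, 75)
        iqr = q3 - q1
        if convention == "quartile_fences":
            lo, hi = q1 - k * iqr, q3 + k * iqr
        else:
            med = quantile_oracle(pool, 50)
            lo, hi = med - k * iqr, med + k * iqr
        for i, (m, r) in enumerate(zip(members, reasons)):
            if r == "" and (m[0] < lo or m[0] > hi):
                reasons[i] = "iqr_fence"
    for i, (m, r) in enumerate(zip(members, reasons)):
        if r == "" and m[3] > cv_max:
            reasons[i] = "pixel_cv"
    return reasons


def mannwhitney_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumerating every assignment of
    the pooled observations to group A (no ties assumed)."""
    from itertools import combinations

    pooled = sorted(list(a) + list(b))
    n_a = len(a)

    def ustat(group_a):
        rest = list(pooled)
        for x in group_a:
            rest.remove(x)
        return sum(1 for x in group_a for y in rest if x > y)

    u_obs = ustat(list(a))
    us = [ustat(list(c)) for c in combinations(pooled, n_a)]
    n = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / n
    p_ge = sum(1 for u in us if u >= u_obs) / n
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def small_dataset():
    """300-probe, single-strain series with planted truth."""
    params = GeneratorParams(
        n_probes=300,
        n_control_probes=20,
        strains=("BALBC",),
        seed=11,
    )
    return generate_dataset(params)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise- and artifact-free series: pipeline output must equal the
    planted truth after flooring."""
    params = GeneratorParams(
        n_probes=200,
        n_control_probes=10,
        replicate_noise_log_sd=0.0,
        outlier_rate=0.0,
        flag_rate=0.0,
        high_cv_rate=0.0,
        strains=("BALBC",),
        experiments=("Exp1",),
        seed=7,
    )
    return generate_dataset(params)


@pytest.fixture()
def metadata_frame():
    def build(tables):
        return pd.DataFrame(
            [(t.sample_id, t.strain, t.subset, t.experiment_id) for t in tables],
            columns=["SampleID", "Strain", "Subset", "ExperimentID"],
        )

    return build
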