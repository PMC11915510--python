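import warnings

import pytest
from hypothesis import HealthCheck, settings

import nucleoquant as nq

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def foci_scene():
    """50 nuclei with 5 foci each at the reference SNR (sigma=3, snr=10)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack, truth = nq.gen_foci_field(50, 5, spot_sigma=3.0, snr=10.0, seed=202)
    return stack, truth


@pytest.fixture(scope="session")
def foci_detection(foci_scene):
    stack, truth = foci_scene
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nuclei = nq.segment_nuclei(stack.plane("hoechst"))
        table = nq.detect_foci(stack.plane("foci"), nuclei)
    return nuclei, table


@pytest.fixture(scope="session")
def fc_eu_groups():
    """Two 10-cell fields per group; treated EU in FCs programmed to 60% of control."""
    import pandas as pd

    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for group, level, seeds in [
            ("control", 100.0, (301, 302)),
            ("treated", 60.0, (303, 304)),
        ]:
            for seed in seeds:
                stack, _ = nq.gen_fc_eu_field(10, eu_fc_level=level, seed=seed)
                nuclei = nq.segment_nuclei(stack.volume("hoechst"))
                dfc = nq.segment_dfc(stack.volume("fib647"), nuclei)
                subs = nq.detect_fc(stack.volume("ubf488"), dfc, nuclei)
                rows = nq.measure_eu(stack.volume("eu594"), subs.fc_labels, nuclei)
                rows["group"] = group
                frames.append(rows)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def timelapse_series():
    """Full imaging pipeline ratios for one control and one treated field (t0=36)."""
    import pandas as pd

    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for group, seed in [("control", 401), ("treated", 402)]:
            stack, _ = nq.gen_timelapse(
                8, 60, r0=1.4, t0=36, tau=10, group=group, seed=seed
            )
            fluor = stack.channel("gfp")[:, 0]
            phase = stack.channel("phase")[:, 0]
            nuc_frames, nol_frames = [], []
            for f in range(fluor.shape[0]):
                nuclei = nq.segment_nuclei(fluor[f])
                nols, _ = nq.detect_nucleoli_phase(phase[f], nuclei)
                nuc_frames.append(nuclei)
                nol_frames.append(nols)
            out.append(
                nq.ratio_timeseries(fluor, nuc_frames, nol_frames, group=group)
            )
    return pd.concat(out, ignore_index=True)
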