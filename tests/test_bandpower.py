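"""iEEG chain: resampling, referencing, Welch spectra, band powers,
contact assignment, and regional reduction."""

import numpy as np
import pandas as pd
import pytest

from epimap.bandpower import (Recording, assign_contacts, band_powers,
                              extract_epoch, ieeg_abnormality, preprocess,
                              regional_band_power, welch_psd)
from epimap.synthetic import BANDS


def sinusoid(freq, fs, dur, n_ch=1, amp=1.0):
    t = np.arange(int(fs * dur)) / fs
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return Recording(data=data, fs=fs,
                     channel_ids=tuple(f"c{i}" for i in range(n_ch)))


def test_common_average_reference_annihilates_common_mode(rng):
    data = np.tile(rng.normal(size=2000), (4, 1))
    rec = Recording(data=data, fs=200.0, channel_ids=("a", "b", "c", "d"))
    out = preprocess(rec)
    assert np.allclose(out.data, 0.0, atol=1e-12)


def test_downsampling_halves_length_and_preserves_sinusoid():
    rec = sinusoid(10.0, 400.0, 20.0)
    out = preprocess(rec, car=False)
    assert out.fs == 200.0
    assert out.data.shape[1] == rec.data.shape[1] // 2
    # amplitude preserved within 1% (compare RMS away from the edges)
    mid = slice(200, -200)
    assert np.sqrt((out.data[0, mid] ** 2).mean()) == pytest.approx(
        np.sqrt(0.5), rel=0.01)


def test_native_rate_passthrough():
    rec = sinusoid(10.0, 200.0, 5.0)
    out = preprocess(rec, car=False)
    assert np.allclose(out.data, rec.data)


def test_upsampling_refused():
    with pytest.raises(ValueError, match="upsample"):
        preprocess(sinusoid(5.0, 100.0, 5.0))


def test_epoch_extraction_arithmetic():
    rec = sinusoid(10.0, 200.0, 100.0)
    ep = extract_epoch(rec, length_s=70.0)
    assert ep.data.shape[1] == 14_000
    with pytest.raises(ValueError, match="too short"):
        extract_epoch(rec, length_s=70.0, offset_s=40.0)


def test_postseizure_criterion_checked_when_metadata_present():
    rec = sinusoid(10.0, 200.0, 100.0)
    with pytest.raises(ValueError, match="postseizure"):
        extract_epoch(rec, epoch_time_s=3600.0, last_seizure_time_s=0.0)
    # compliant timing passes
    extract_epoch(rec, epoch_time_s=8000.0, last_seizure_time_s=0.0)


def test_welch_sinusoid_parseval():
    rec = sinusoid(10.0, 200.0, 70.0)
    freqs, psd = welch_psd(rec)
    assert freqs[1] - freqs[0] == pytest.approx(0.5)
    total = psd[0].sum() * 0.5
    assert total == pytest.approx(0.5, rel=0.05)          # variance of sin
    assert freqs[np.argmax(psd[0])] == pytest.approx(10.0, abs=0.5)


def test_welch_white_noise_variance(rng):
    sigma = 2.0
    rec = Recording(data=sigma * rng.standard_normal((1, 14_000)), fs=200.0,
                    channel_ids=("c0",))
    freqs, psd = welch_psd(rec)
    assert psd[0].sum() * 0.5 == pytest.approx(sigma ** 2, rel=0.10)


def test_dc_free_input_has_no_zero_frequency_power():
    rec = sinusoid(10.0, 200.0, 10.0)
    freqs, psd = welch_psd(rec)
    assert psd[0, 0] < 1e-10 * psd[0].max()


def test_band_power_edges_and_normalization(rng):
    # synthetic PSD entirely inside alpha
    freqs = np.arange(0, 100.5, 0.5)
    psd = np.zeros((1, len(freqs)))
    psd[0, (freqs >= 9) & (freqs < 12)] = 1.0
    bp = band_powers(freqs, psd, ("c0",))
    rel = bp.set_index("band")["rel_power"]
    assert rel["alpha"] == pytest.approx(1.0)
    assert rel.drop("alpha").max() == 0.0
    # equal power in all five bands -> 0.2 each
    psd2 = np.ones((1, len(freqs)))
    widths = {b: hi - lo for b, (lo, hi) in
              {"delta": (1, 4), "theta": (4, 8), "alpha": (8, 13),
               "beta": (13, 30), "gamma": (30, 80)}.items()}
    for b, (lo, hi) in {"delta": (1, 4), "theta": (4, 8), "alpha": (8, 13),
                        "beta": (13, 30), "gamma": (30, 80)}.items():
        psd2[0, (freqs >= lo) & (freqs < hi)] = 1.0 / widths[b]
    bp2 = band_powers(freqs, psd2, ("c0",))
    assert np.allclose(bp2["rel_power"], 0.2, atol=1e-9)


def test_relative_powers_sum_to_one_for_random_recordings(rng):
    data = rng.standard_normal((6, 14_000))
    rec = Recording(data=data, fs=200.0,
                    channel_ids=tuple(f"c{i}" for i in range(6)))
    freqs, psd = welch_psd(rec)
    bp = band_powers(freqs, psd, rec.channel_ids)
    sums = bp.groupby("contact_id")["rel_power"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_zero_power_rejected():
    freqs = np.arange(0, 100.5, 0.5)
    with pytest.raises(ValueError, match="zero total"):
        band_powers(freqs, np.zeros((1, len(freqs))), ("c0",))


def test_pipeline_invariances(rng):
    """Relative band power is invariant to channel order and to global
    amplitude scaling."""
    data = rng.standard_normal((3, 14_000))
    ids = ("a", "b", "c")
    def rel(d, ids):
        freqs, psd = welch_psd(Recording(data=d, fs=200.0, channel_ids=ids))
        return band_powers(freqs, psd, ids).set_index(["contact_id", "band"])["rel_power"]
    base = rel(data, ids)
    scaled = rel(7.3 * data, ids)
    reordered = rel(data[::-1], ids[::-1])
    assert np.allclose(base, scaled, atol=1e-12)
    assert np.allclose(base.sort_index(), reordered.sort_index(), atol=1e-12)


def test_pure_sinusoid_concentrates_in_its_band():
    rec = sinusoid(20.0, 200.0, 70.0)       # interior of beta
    freqs, psd = welch_psd(rec)
    bp = band_powers(freqs, psd, rec.channel_ids)
    assert bp.set_index("band")["rel_power"]["beta"] >= 0.95


def test_contact_assignment_rules():
    geometry = {"roiA": np.array([[0.0, 0.0, 0.0]]),
                "roiB": np.array([[20.0, 0.0, 0.0]])}
    contacts = pd.DataFrame([
        {"contact_id": "near_a", "x_mm": 3.0, "y_mm": 0.0, "z_mm": 0.0,
         "tissue": "GM"},
        {"contact_id": "far", "x_mm": 10.0, "y_mm": 8.0, "z_mm": 0.0,
         "tissue": "GM"},
        {"contact_id": "wm_close", "x_mm": 1.5, "y_mm": 0.0, "z_mm": 0.0,
         "tissue": "WM"},
        {"contact_id": "wm_far", "x_mm": 3.0, "y_mm": 0.0, "z_mm": 0.0,
         "tissue": "WM"},
        {"contact_id": "bad", "x_mm": 0.5, "y_mm": 0.0, "z_mm": 0.0,
         "tissue": "GM", "artifact": True},
    ])
    out = assign_contacts(contacts, geometry).set_index("contact_id")
    assert out.loc["near_a", "roi_id"] == "roiA"
    assert out.loc["far", "exclusion_reason"] == "far_from_any_region"
    assert out.loc["wm_close", "roi_id"] == "roiA"
    assert out.loc["wm_far", "exclusion_reason"] == "wm_far_from_gm"
    assert out.loc["bad", "exclusion_reason"] == "artifact"


def test_regional_mean_and_coverage():
    bp = pd.DataFrame({
        "contact_id": ["c0", "c1"], "band": ["alpha", "alpha"],
        "power": [1.0, 1.0], "rel_power": [0.3, 0.5],
        "log10_rel_power": [np.log10(0.3), np.log10(0.5)]})
    assignment = pd.DataFrame({"contact_id": ["c0", "c1"],
                               "roi_id": ["roiA", "roiA"],
                               "distance_mm": [1.0, 1.0],
                               "exclusion_reason": ["none", "none"]})
    out = regional_band_power(bp, assignment, rois=["roiA", "roiB"])
    a = out[(out["roi_id"] == "roiA") & (out["band"] == "alpha")]
    assert a["value"].iloc[0] == pytest.approx(
        (np.log10(0.3) + np.log10(0.5)) / 2)
    b = out[out["roi_id"] == "roiB"]
    assert (b["coverage"] == "unsampled").all()
    assert b["value"].isna().all()


def test_max_abs_z_reduction():
    zmap = pd.DataFrame({
        "patient_id": "p0", "roi_id": "r0",
        "band": ["delta", "theta", "alpha", "beta", "gamma"],
        "z": [1.0, -3.2, 0.5, 2.0, -0.1]})
    out = ieeg_abnormality(zmap)
    assert out["score"].iloc[0] == pytest.approx(3.2)
    assert out["band"].iloc[0] == "theta"
    assert out["signed_z"].iloc[0] == pytest.approx(-3.2)
    zero = zmap.assign(z=0.0)
    assert ieeg_abnormality(zero)["score"].iloc[0] == 0.0
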