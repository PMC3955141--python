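"""Test-retest reproducibility on duplicate baseline scans.

Computes per-lesion percentage differences (Scan2 vs Scan1 relative to the
pair mean), then the SD across lesions and the repeatability coefficient
RC = 1.96 x SD: the change a response must exceed to be distinguishable from
measurement noise. The size-dependence diagnostic asks whether |difference|
correlates (negatively) with lesion size.
"""

from fltpet import generate_cohort, reference_cohort_config, size_dependence, summarize_reproducibility
from fltpet.reproducibility import build_test_retest_records

cohort = generate_cohort(reference_cohort_config(seed=11))
records = build_test_retest_records(cohort)

for param in ("volume", "suv_mean", "suv_max"):
    s = summarize_reproducibility(records, param, "all")
    print(
        f"{param:>8}: mean diff {s.mean_diff_pct:+5.1f}%  SD {s.sd_diff_pct:4.1f}%  "
        f"|diff| {s.abs_repro_pct:4.1f}%  RC {s.rc_pct:4.1f}%  (n={s.n})"
    )

r = size_dependence(records, "volume")
print(f"volume size-dependence: Spearman rho {r.rho:+.2f} (p={r.p_two_sided:.3f})")
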