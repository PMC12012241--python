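"""Scoring automated paths against a surgeon's plan.

Given per-case angle and target-distance metrics, `summarize` reports the
column means, sds, and a paired t-test between L1 and L2.  The five-case
values below are the printed results of the source clinical evaluation,
used here as a worked example: they reproduce its summary statistics —
mean L2 angle 16.36 deg, mean L1 target distance 16.98 mm, mean L2 target
distance ~9 mm.
"""

from hemoplan import CaseComparison, summarize

cases = [
    CaseComparison(case_id=str(i + 1), angle_L1_deg=a1, angle_L2_deg=a2,
                   target_dist_L1_mm=d1, target_dist_L2_mm=d2)
    for i, (a1, a2, d1, d2) in enumerate(
        zip(
            [40.28, 60.02, 116.78, 43.36, 76.45],
            [5.50, 13.33, 10.67, 5.20, 47.12],
            [8.31, 15.52, 10.02, 27.5, 23.54],
            [5.20, 7.03, 3.54, 13.55, 15.53],
        )
    )
]
report = summarize(cases)
print(f"mean angle  L1 vs manual : {report.means['angle_L1_deg']:.2f} deg")
print(f"mean angle  L2 vs manual : {report.means['angle_L2_deg']:.2f} deg")
print(f"mean target dist L1      : {report.means['target_dist_L1_mm']:.2f} mm")
print(f"mean target dist L2      : {report.means['target_dist_L2_mm']:.2f} mm")
t = report.paired_t["angle_L1_vs_L2"]
print(f"paired t (angles, L1 vs L2): t = {t['t']:.3f}, p = {t['p_two_sided']:.4f}, n = {t['n']}")
# A significant p (< 0.05) means the quadrant-guided L2 direction tracks
# the surgeon's chosen approach markedly better than the raw axis path L1.
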