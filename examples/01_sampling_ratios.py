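"""Section-sampling ratios of printed stereotaxic atlases.

Printed atlases annotate regions only on a subset of 40-um sections.  From
each region's rostral and caudal Bregma ends and its number of annotated
plates, this recomputes the estimated total section count and the sampling
ratio, and compares them with the published table values.
"""

from atlasoverlap.extent_tables import (
    BRAIN_MAPS_V3,
    RAT_STEREOTAXIC_V6,
    mean_ratio_pct,
    sampling_table,
)

for table in (RAT_STEREOTAXIC_V6, BRAIN_MAPS_V3):
    frame = sampling_table(table)
    print(f"\n{table.atlas_name} (version {table.version_label})")
    print(
        frame[
            ["abbreviation", "rostral_mm", "caudal_mm", "n_sampled",
             "total_sections", "ratio_pct", "published_ratio_pct"]
        ].head(6).to_string(index=False)
    )
    exact = (
        (frame.total_sections == frame.published_total_sections)
        & (frame.ratio_pct == frame.published_ratio_pct)
    ).sum()
    print(f"rows matching the published table exactly: {exact}/{len(frame)}")
    print(f"mean sampling ratio: {mean_ratio_pct(table)}%")

print(
    "\nA ratio of e.g. 34% means only about a third of the 40-um sections"
    "\nspanning that region carry annotations in the printed atlas."
)
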