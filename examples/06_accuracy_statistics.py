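"""Confusion-matrix statistics and coverage-error arithmetic on printed counts.

Feeds a published wheat/soil validation matrix and published coverage pairs
through the accuracy battery; these numbers need no imagery, only the
counts, so they double as a check of the statistics themselves.
"""

from vegcover import ConfusionMatrix2x2, confusion_stats, extraction_errors

cm = ConfusionMatrix2x2(n_vv=29611, n_vs=140, n_sv=157, n_ss=22405)
s = confusion_stats(cm)
print("validation confusion matrix (wheat vs soil):")
print(f"  user's accuracy     : wheat {s.users_accuracy_veg:.4f}, "
      f"soil {s.users_accuracy_soil:.4f}")
print(f"  producer's accuracy : wheat {s.producers_accuracy_veg:.4f}, "
      f"soil {s.producers_accuracy_soil:.4f}")
print(f"  overall accuracy    : {s.overall_accuracy:.4f}")
print(f"  Cohen's kappa       : {s.kappa:.4f}")

rep = extraction_errors(
    [("crop", 85.14, 85.78), ("tree", 73.96, 73.77),
     ("shrub", 61.28, 60.02), ("mixed", 73.62, 75.13)], index_name="EXG")
print("\nEXG coverage errors across vegetation types:")
print(rep.table[["vegetation_type", "extraction_error_pct",
                 "absolute_error_points"]].round(2).to_string(index=False))
print(f"SD of absolute errors: {rep.abs_error_sd:.2f}")
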