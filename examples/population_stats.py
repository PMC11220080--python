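"""Population-level statistics: cumulative abundance change and phase structure.

Computes the percent change in cumulative daily abundance of every whole-cell
protein between conditions, compares the rhythmic sub-population against all
proteins with a pooled-variance t-test, and summarizes the acrophase
distribution of the rhythmic population.
"""

from rerhythm import (
    SimConfig,
    compare_populations,
    cumulative_change_matrix,
    detect_rhythms,
    generate_multiomics,
    phase_histogram,
)

ds = generate_multiomics(SimConfig(n_genes=300, seed=33, amplitude_mean=1.0,
                                   amplitude_floor=0.5))
m_std, m_ecd = ds.matrices[("STD", "TE")], ds.matrices[("ECD", "TE")]

change = cumulative_change_matrix(m_std, m_ecd).dropna()
fits = detect_rhythms(m_std, use_q=False, n_perm=1000, seed=2)
rhythmic = fits.index[fits["consensus_rhythmic"]]

r = compare_populations(change.loc[rhythmic].to_numpy(), change.to_numpy())
print(f"mean cumulative daily abundance change, all proteins: {r.group_b_mean:+.1f}%")
print(f"mean change, STD-rhythmic proteins:                   {r.group_a_mean:+.1f}%")
print(f"pooled-variance t test: t = {r.t_statistic:.2f}, p = {r.p_value:.3f}")
# a small p flags a distribution shift in the rhythmic sub-population: losing a
# rhythm lowers linear-scale cumulative abundance slightly (2^x is convex, so a
# flat log2 profile integrates to less material than an oscillating one)

counts, mean_h, resultant = phase_histogram(fits.loc[rhythmic, "acrophase"])
print("acrophase histogram (3-h bins):", counts.to_numpy().tolist())
print(f"circular mean CT{mean_h:.1f}, resultant length {resultant:.2f} "
      "(0 = phases spread uniformly, 1 = fully synchronous)")
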