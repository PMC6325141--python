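# Cellular constants: Saccharomyces cerevisiae, rapid growth (rich medium).
organism_label: "S. cerevisiae"
N_m: 60000            # mRNAs per cell
N_p: 1.1e+8           # proteins per cell (3e6 per um^3 x 37 um^3)
mu: 0.42              # growth rate, h^-1 (99 min division time: 60*ln2/99)
alpha_deg: 0.924      # protein degradation, h^-1 (45 min half-life: 60*ln2/45)
alpha_p: 1.34         # protein decay = degradation + dilution, h^-1
alpha_m: 5.1          # median mRNA decay, h^-1
cv0: 0.10             # protein-abundance noise floor (dimensionless CV)
l_m: 1300             # typical (pre-)mRNA length, nt
total_transcription: 3.06e+5   # sum of beta_m = N_m * alpha_m, mRNA h^-1
v: 10.0               # ribosome elongation speed, aa s^-1
footprint_nt: 28      # ribosome footprint, nt (L = 9.3 codons)
beta_p_max: 7.1e+3    # top percentile of measured translation rates, protein mRNA^-1 h^-1
rho: 1.0              # fitness-contribution fraction (essential-gene bound)
reference:            # published values, metadata only -- never fed into computations
  measured_k: 1.1
  measured_k_se: 0.1
  predicted_k: 1.1
  predicted_k_se: 0.3
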