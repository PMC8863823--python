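# Example ifnscan pipeline configuration.
# `ifnscan run --config config.example.yaml`

output_dir: ifnscan_out
seed: 42

# --- input: synthetic simulation (set synthetic: false and provide
# genome_fasta / annotation_gff3 to scan a real assembly) ---------------
synthetic: true
n_pos: 8
n_decoy: 16
genome_len: 2000000
gc: 0.4
# genome_fasta: genome.fasta
# annotation_gff3: annotation.gff3
min_intergenic: 200

# --- constrained gene search ------------------------------------------
search:
  min_exon: 30
  max_exon: 600
  min_intron: 60     # compact synthetic intron class; widen for real genomes
  max_intron: 70
  min_protein: 120
  max_protein: 250
  n_exons: 5
  strands: both

# --- protein feature screen (defaults shown) ---------------------------
features:
  sp_h_window: 8
  sp_h_threshold: 1.5
  sp_cleavage_min: 15
  sp_cleavage_max: 35
  helix_window: 7
  helix_threshold: 1.03
  helix_min_segment: 7
  min_helix_segments: 4
  tm_window: 19
  tm_threshold: 1.6
  tm_min_run: 15

# --- downstream placement ----------------------------------------------
# reference_fastas:           # protein FASTA per family (omit in synthetic
#   type_I_IFN: refs/ifn1.faa #  mode: families are simulated)
phylo_reps: 100               # bootstrap replicates (1000 for final trees)
phylo_correction: p           # p | poisson
synteny_k: 5
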