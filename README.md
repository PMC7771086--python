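# subsites

Annotation, modelling and Monte Carlo analysis of protease–peptide
complexes across the **S4–S4′ binding pockets**.

Proteases recognise their substrates through a row of surface pockets
(subsites) labelled S4–S1 on the non-prime side and S1′–S4′ on the prime
side of the scissile bond; the substrate residues that occupy them are
labelled P4–P1 and P1′–P4′. `subsites` is a toolkit for researchers who
want to connect the *structural* signature of this recognition — burial,
hydrogen bonding, packing, interaction energy at each substrate position —
with the *informational* signature encoded in experimental specificity
matrices.

The package implements an automated workflow:

1. **Annotate** — find peptide-like ligands (3–12 residues) in a
   protease structure, confirm they occupy the catalytic site (the summed
   accessible surface of the catalytic residues must increase strictly
   above 0 Å² when the ligand is removed), and assign each peptide
   residue to a pocket: every protease residue with an atom within
   4.5 Å of a reference substrate residue joins that residue's pocket.
   Annotations are projected onto homologous complexes through a
   sequence-guided CA superposition (a residue inherits the pocket of the
   reference residue with the most atoms within 2 Å), label gaps are
   closed by moving the shorter assigned run, capping groups (acetyl,
   diazomethane) are stripped, and substrates with fewer than three
   pocket residues are discarded. Catalytic residues can be inferred by
   homology transfer when a global alignment exceeds 50 % identity.
2. **Model** — replace a non-natural amino acid by its most similar
   natural counterpart (Morgan-fingerprint Tanimoto similarity), rebuild
   side chains with ideal geometry, extend partial peptides to full
   P4–P4′ 8-mers with ideal backbone geometry and a clash-scanned
   φ/ψ grid, and thread random peptide libraries (default 480 8-mers,
   uniform over the 20 amino acids at every position) onto the template
   by iterative single mutations.
3. **Sample** — Metropolis Monte Carlo with backrub-style backbone moves
   (rigid rotation of a 2–12 residue segment about the axis through its
   flanking CA atoms) and Gaussian side-chain moves, under a pluggable
   energy model (12-6 Lennard-Jones, distance-dependent-dielectric
   Coulomb, geometric hydrogen-bond bonus). Default 5000 steps at
   kT = 1.2 with a frame every 10 steps → 500 frames.
4. **Observe** — per frame and per position: relative accessible surface
   area (Shrake–Rupley, against Gly-X-Gly theoretical maxima), hydrogen
   bonds and non-bonded contacts split into main-/side-chain, and the
   per-position interface energy. Averages over runs α and frames f give
   O_ij = (1/N_f) Σ_α Σ_f o_ij^{αf}.
5. **Compare** — per-position cleavage entropy from a specificity matrix,

   H(j) = −Σ_{i=1..20} n_ij · log₂₀(n_ij),  H_cleavage = Σ_{j=1..8} H(j),

   where n_ij is the occurrence fraction of amino acid i at position j
   (H(j)=0: absolute preference; H(j)=1: equal usage; H_cleavage ∈ [0,8]),
   followed by the average per-position Spearman correlation between the
   observable profiles and H(j).

A fixtures module builds deterministic toy protease–peptide grooves with
ground-truth pocket assignments so the whole pipeline runs and tests
without any downloaded structure.

## Worked example

```sh
subsites fixtures --out fx
subsites pipeline fx/toy_complex.pdb \
    --catalytic fx/toy_catalytic.tsv \
    --reference-positions fx/toy_reference_positions.tsv \
    --matrix fx/toy_matrix.tsv \
    --out run --library-n 4 --steps 200 --seed 3
```

prints `kept=1 discarded=0 out=run` and writes per-stage tables under
`run/`. The per-position summary (`run/summary.tsv`) from that exact
command contains, for the relative accessible surface area:

```
observable  position  mean      normalized
rel_asa     P4        0.458368  0.915549
rel_asa     P3        0.273611  0.444119
rel_asa     P2        0.327406  0.581384
rel_asa     P1        0.099559  0.000000
rel_asa     P1'       0.297013  0.503832
rel_asa     P2'       0.270666  0.436604
rel_asa     P3'       0.278671  0.457030
rel_asa     P4'       0.491464  1.000000
```

P1 is the most buried position (relative ASA 0.10, normalized 0 across
the eight positions) and also carries the most favourable interface
energy (−0.04 internal units versus +0.15…+3.1 elsewhere) — the
signature of the deep S1 pocket built into the fixture. Termini (P4,
P4′) are the most exposed. `run/entropy.tsv` holds H(j) for the supplied
matrix and `run/correlations.tsv` the per-observable Spearman values.

The same subcommands (`annotate`, `library`, `sample`, `entropy`,
`pipeline`) accept downloaded PDB entries and MEROPS-style matrices as
plain files; a discard manifest (`discards.tsv`) records every structure
that a filter removed, with the reason.

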