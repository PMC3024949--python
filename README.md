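# tfbsevol

Inference of the gain and loss of transcription-factor binding sites (TFBS)
across species — the "evolution of gene regulation" seen from the DNA side.

Regulatory regions evolve fast: most predicted binding sites turn over
between lineages, which makes the sites that *are* conserved, or that arise
at a datable point in phylogeny, the interesting ones. `tfbsevol` provides
the desk-scale toolchain for that question, built around the three
pluripotency regulators Oct4 (Pou5f1), Sox2 and Nanog as its packaged
worked example:

1. **Curated-site tables.** A literature-curated table of experimentally
   validated binding sites (factor, citation key, mm9 interval, verification
   marker) is parsed, checked against reference sequence (exact match,
   reverse-complement match, or mismatch) and exported as UCSC custom
   tracks. The packaged table covers the Oct4/Sox2/Nanog regulatory regions
   and draws on 39 distinct publications.
2. **Motif scanning.** JASPAR-style count matrices become log-odds
   position-specific scoring matrices (PSSMs); both strands of a sequence
   are scanned and every window score is assigned an *exact* p-value under
   the background model, computed by dynamic programming over a discretized
   score lattice, plus an E-value over the scanned windows.
3. **Homology grouping.** Hits found per species are projected into the
   column space of the multiple alignment of the orthologous region; hits of
   homologous factors with essentially the same coordinates (reciprocal
   column overlap ≥ 0.5, single linkage) become one binary
   presence/absence character per species.
4. **Parsimony.** Each character is reconstructed on a rooted species tree
   by small parsimony (binary Sankoff DP with DELTRAN/ACCTRAN resolution);
   gains and losses are read off the edges.
5. **Modules and ranking.** Characters gained (or lost) on the same edge
   form a candidate cis-regulatory module, scored by the branch length
   score and emitted as ranked UCSC tracks.
6. **Simulation.** A generator evolves a region along a tree (Jukes-Cantor
   substitution, no indels) with planted motif gain/loss events, so the
   whole pipeline is testable against known truth.

## The statistics in brief

For a count matrix `n` with column sums `N_i`, background `b` and
pseudocount `c`, position `i` scores base `x` (in bits)

    s_i(x) = log2( (n_ix + c·b_x) / (N_i + c) / b_x )

and a window `w` scores `S(w) = Σ_i s_i(w_i)`. The p-value of a score `S`
is `P(S(W) ≥ S)` for a random background word `W`, computed exactly on a
1/1000-bit score lattice; the E-value multiplies by `2·(number of N-free
windows)`.

For a character with present-leaf set `P` on tree `T`, the branch length
score is

    BLS = len(minimal subtree of T connecting P) / len(T)

so a site present everywhere scores 1, a species-specific site scores 0.

## Worked example

Simulate a 500 bp region on a six-species mammal tree with a strong 14 bp
site gained on the edge leading to the human+macaque+mouse+rat clade, then
run the full inference:

```python
from tfbsevol.simulate import default_gain_config, simulate_region
from tfbsevol.pipeline import infer_site_evolution
from tfbsevol.modules import modules_to_tsv

config = default_gain_config(seed=7)
alignment, truth = simulate_region(config)
result = infer_site_evolution(alignment, config.tree,
                              list(config.motifs.values()), pvalue=1e-4)
for c in result.characters:
    print(c.character_id, dict(c.presence))
lab = result.labelings[result.characters[0].character_id]
print("gains:", lab.gains, "losses:", lab.losses)
print(modules_to_tsv(result.modules))
```

prints

```
simTF:000240 {'human': 1, 'macaque': 1, 'mouse': 1, 'rat': 1, 'dog': 0, 'opossum': 0}
gains: ('euarchontoglires',) losses: ()
module_id	edge	type	members	bls	rank
gain@euarchontoglires	euarchontoglires	gain	simTF:000240	0.545455	1
```

One character was found at region offset 240 (exactly where the site was
planted), present in the four species below the planted edge; parsimony
dates the gain to the `euarchontoglires` edge; the resulting singleton
module spans 6 of the 11 branch-length units of the tree (BLS 0.545) and
ranks first.

The same stages are available from the shell:

```
tfbsevol curated-bed --out sites.bed          # packaged curated table -> UCSC track
tfbsevol scan --matrices m.txt --fasta s.fa --pvalue 1e-4 --out hits.tsv
tfbsevol simulate --config sim.yaml --out-dir sim/
tfbsevol pipeline --alignment aln.fa --tree tree.nwk --matrices m.txt --out-dir out/
```

## Layout

- `src/tfbsevol/curation.py` — curated tables, verification, BED export
- `src/tfbsevol/motifs.py` — PSSMs, scanning, exact p-values
- `src/tfbsevol/homology.py` — alignment projection, character building
- `src/tfbsevol/parsimony.py` — species trees, Sankoff/Fitch reconstruction
- `src/tfbsevol/modules.py` — branch length score, module ranking
- `src/tfbsevol/tracks.py` — UCSC custom-track output
- `src/tfbsevol/simulate.py`, `fixtures.py` — simulator and packaged data
- `src/tfbsevol/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — models, parameters, numerical choices, limitations
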