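# wchrom

Detection of female-specific (W-chromosome) sequence in a genome with
homomorphic sex chromosomes, from the read-depth ratio of sex-pooled
low-coverage resequencing panels — together with the supporting procedures
such a study needs: assigning assembly scaffolds to a laser-captured
chromosome, per-chromosome synteny enrichment, sex-marker panel statistics,
and derived-substitution counting between a gene and its young sex-linked
duplicate.

## The problem and the method

In a ZW system, sequence that exists only on the W chromosome is hemizygous:
one copy in females, zero in males. When whole-genome reads from many sexed
individuals are pooled per sex and aligned to a female reference, W-specific
loci show roughly half the female modal depth and (ideally) no male reads,
while the diploid background shows equal adjusted coverage in both sexes.
`wchrom` turns that contrast into interval calls:

1. **Depth and pooling** (`wchrom.covprof`). Per-base depth is computed from
   coordinate-sorted alignments after excluding unmapped, secondary and
   supplementary records (SAM flag mask 2308) and alignments clipped at both
   ends, then summed per sex. Each pooled track is summarised by its modal
   non-zero depth `modal_f`, `modal_m`.
2. **Valid bases** (`wchrom.wscan`). A base with pooled depths `C_f`, `C_m`
   is *valid* iff `(C_f < max_f and C_m < max_m) and (C_f > min_f or
   C_m > min_m)`, with `min = floor(modal/3)` and `max = 3 * modal` per sex.
   Upper limits skip collapsed repeats; lower limits skip uninformative
   low-coverage bases.
3. **Interval scan.** Each scaffold's valid bases are chunked into
   consecutive intervals of `V = 1000` valid bases (shorter at scaffold
   ends) and every interval receives an enrichment score
   `log2( mean_f / (a * mean_m) )`, means over valid bases, with the
   male-coverage adjustment `a = modal_f / modal_m`. A male mean of exactly
   zero is replaced by the depth of half of one read,
   `(read_length/2) / span`. Intervals spanning < 500 bp or holding < 200
   valid bases are dropped; a score strictly above 2 (a > 4-fold female
   excess) calls a W-candidate.

Because no public dataset is needed to exercise the method, the package
ships a first-class synthetic generator (`wchrom.simgen`): genomes tiled
with autosomal, W-specific, Z-hemizygous, collapsed-repeat and
deletion-polymorphism segments, and per-individual Poisson depth (or placed
SAM reads) with mean `target_depth * copy_number/2 * repeat_multiplier`.
Truth BEDs make recovery measurable.

The companion modules are `wchrom.chromassign` (scaffold-to-chromosome
assignment when ≥ 5% of a scaffold is under the union of concordant,
mismatch-free read-pair fragments from a laser-captured chromosome library),
`wchrom.syntenyscore` (homolog calls at ≥ 50 aa and ≥ 60% identity;
enrichment = observed homologs / annotated genes per chromosome),
`wchrom.sextype` (marker-panel classification, the `p^nf (1-p)^nm` panel
false-positive probability, Z/W Punnett expectations, biplex PCR sex calls)
and `wchrom.paralogdiv` (outgroup-parsimony attribution of derived
substitutions between paralogs, pairwise identity).

## Worked example

Simulate a small sexed panel, pool it, and scan:

```sh
cat > cfg.json <<'EOF'
{"n_scaffolds": 4, "scaffold_length": 20000, "n_w_segments": 2, "n_z_segments": 1,
 "n_repeat_segments": 1, "n_indel_segments": 1, "n_females": 3, "n_males": 3,
 "target_depth": 4.0, "seed": 5}
EOF
wchrom simulate --config cfg.json --outdir simout
printf 'scaffold_0\t20000\nscaffold_1\t20000\nscaffold_2\t20000\nscaffold_3\t20000\n' > lengths.tsv
wchrom pool --panel simout/panel.tsv --lengths lengths.tsv --outdir poolout
wchrom scan --female poolout/pooled_female.bedgraph --male poolout/pooled_male.bedgraph \
            --lengths lengths.tsv --n-females 3 --n-males 3 --outdir scanout
wchrom cross --p1 ZW --p2 ZW
```

prints

```
modal_f=11 modal_m=12 adjustment=0.9167
2 candidate intervals on 2 scaffolds (1 with zero male reads, 2321 bp total)
P(female)=0.75 P(male)=0.25 female:male=3:1
```

Three females at ~4X give a pooled female mode of 11 (12 for the larger male
pool), so male coverage is scaled by 11/12 before ratio formation. The two
candidate intervals (`scanout/candidates.bed`, score in column 5) recover
the two planted 2-kb W-specific segments:

```
scaffold_2	11000	12152	candidate	2.2996
scaffold_3	8125	9294	candidate	7.0805
```

The second candidate has zero male reads, so its score comes from the
half-read substitution. The last line is the Mendelian expectation for a
cross between a sex-reversed ZW male and a ZW female with WW viable: three
females per male.

In the library the same pipeline is `simgen.build_genome_model` +
`simulate_pooled`, `covprof.SexCoverageProfile.from_pooled` +
`derive_limits`, and `wscan.run_scan`.

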