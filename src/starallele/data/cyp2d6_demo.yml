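# CYP2D6-style demo cluster: a 19-region gene and one highly homologous
# pseudogene, with whole-gene, fusion, exon-conversion, partial-deletion
# and whole-deletion structural configurations.  All coordinates, region
# sizes and allele definitions are SYNTHETIC illustrative stand-ins that
# mimic the *shape* of the real locus (including a long gene<->pseudogene
# identical stretch between exon 6 and exon 9); no clinical content.
schema: 1
gene: CYP2D6_DEMO
pseudogenes: [CYP2D7_DEMO]
regions:
  CYP2D6_DEMO:
    - {kind: intron, ordinal: 1, span: [0, 200]}
    - {kind: exon, ordinal: 1, span: [200, 300]}
    - {kind: intron, ordinal: 2, span: [300, 500]}
    - {kind: exon, ordinal: 2, span: [500, 600]}
    - {kind: intron, ordinal: 3, span: [600, 800]}
    - {kind: exon, ordinal: 3, span: [800, 900]}
    - {kind: intron, ordinal: 4, span: [900, 1100]}
    - {kind: exon, ordinal: 4, span: [1100, 1200]}
    - {kind: intron, ordinal: 5, span: [1200, 1400]}
    - {kind: exon, ordinal: 5, span: [1400, 1500]}
    - {kind: intron, ordinal: 6, span: [1500, 1700]}
    - {kind: exon, ordinal: 6, span: [1700, 1800]}
    - {kind: intron, ordinal: 7, span: [1800, 2000]}
    - {kind: exon, ordinal: 7, span: [2000, 2100]}
    - {kind: intron, ordinal: 8, span: [2100, 2300]}
    - {kind: exon, ordinal: 8, span: [2300, 2400]}
    - {kind: intron, ordinal: 9, span: [2400, 2600]}
    - {kind: exon, ordinal: 9, span: [2600, 2700]}
    - {kind: intron, ordinal: 10, span: [2700, 2900]}
  CYP2D7_DEMO:
    - {kind: intron, ordinal: 1, span: [3000, 3200]}
    - {kind: exon, ordinal: 1, span: [3200, 3300]}
    - {kind: intron, ordinal: 2, span: [3300, 3500]}
    - {kind: exon, ordinal: 2, span: [3500, 3600]}
    - {kind: intron, ordinal: 3, span: [3600, 3800]}
    - {kind: exon, ordinal: 3, span: [3800, 3900]}
    - {kind: intron, ordinal: 4, span: [3900, 4100]}
    - {kind: exon, ordinal: 4, span: [4100, 4200]}
    - {kind: intron, ordinal: 5, span: [4200, 4400]}
    - {kind: exon, ordinal: 5, span: [4400, 4500]}
    - {kind: intron, ordinal: 6, span: [4500, 4700]}
    - {kind: exon, ordinal: 6, span: [4700, 4800]}
    - {kind: intron, ordinal: 7, span: [4800, 5000]}
    - {kind: exon, ordinal: 7, span: [5000, 5100]}
    - {kind: intron, ordinal: 8, span: [5100, 5300]}
    - {kind: exon, ordinal: 8, span: [5300, 5400]}
    - {kind: intron, ordinal: 9, span: [5400, 5600]}
    - {kind: exon, ordinal: 9, span: [5600, 5700]}
    - {kind: intron, ordinal: 10, span: [5700, 5900]}
cn_neutral_region: [6000, 6400]
read_model: {read_length: 100, insert_size: 300}
# the stretch from the end of exon 6 to the start of exon 9 is identical
# between the two units and longer than one fragment span -> masked
identity_segments:
  - [1800, 2600]
  - [4800, 5600]
mutations:
  - {pos: 1150, op: "C>T", class: gene_disrupting}
  - {pos: 1450, op: "G>A", class: gene_disrupting}
  - {pos: 250, op: "G>A", class: gene_disrupting}
  - {pos: 220, op: "C>T", class: gene_disrupting}
  - {pos: 50, op: "C>A", class: neutral}
  - {pos: 700, op: "T>C", class: neutral}
  - {pos: 950, op: "T>G", class: neutral}
  - {pos: 1250, op: "A>C", class: neutral}
  - {pos: 1350, op: "G>C", class: neutral}
  - {pos: 2650, op: "G>T", class: neutral}
configs:
  gene: {vector: [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]}
  pseudo: {vector: [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]}
  fusion_e2: {vector: [1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]}
  conversion_e9: {vector: [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0]}
  partial_del: {vector: [1, 1, 1, 1, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]}
  deletion: {deletion: true}
majors:
  "*1": {config: gene, gdm: []}
  "*2": {config: gene, gdm: ["1150:C>T", "1450:G>A"]}
  "*4": {config: gene, gdm: ["250:G>A"]}
  "*5": {config: deletion, gdm: []}
  "*10": {config: gene, gdm: ["220:C>T"]}
  "*36": {config: conversion_e9, gdm: ["220:C>T"]}
  "*41": {config: gene, gdm: ["1150:C>T"]}
  "*68": {config: fusion_e2, gdm: ["220:C>T"]}
minors:
  "*1A": {major: "*1", neutral: []}
  "*1B": {major: "*1", neutral: ["700:T>C"]}
  "*2A": {major: "*2", neutral: ["1250:A>C"]}
  "*2B": {major: "*2", neutral: ["1250:A>C", "2650:G>T"]}
  "*4A": {major: "*4", neutral: ["950:T>G"]}
  "*4C": {major: "*4", neutral: ["50:C>A"]}
  "*41A": {major: "*41", neutral: ["1350:G>C"]}
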