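# Synthetic locus presets, ORC-anchored closed coordinates (position 0 =
# first nucleotide of the T-rich strand of the ORC site).
#
# Element consensus strings are synthetic stand-ins written from the
# field-standard consensus of each binding factor; they are not extracted
# from any genome or database.
ars317_like:
  length: 400
  upstream: 160
  orc_site: TTTTATGTTTAGTTTTA
  orc_rf_effect: 0.20
  orc_pf_effect: 0.00
  rf_base: 0.60
  pf_base: 0.05
  elements:
    - label: RAP1
      start: -30
      end: -18
      consensus: ACACCCATACATT
      rf_effect: 0.00
      pf_effect: 0.90
    - label: FKH
      start: 60
      end: 80
      consensus: GTAAACAAAGTAAACAAAGTA
      rf_effect: 0.05
      pf_effect: 0.00

ars301_like:
  # The full-fragment reference for this preset spans -42..+92 (135 bp).
  length: 400
  upstream: 160
  orc_site: TTTTATGTTTAGTTTTA
  orc_rf_effect: 0.15
  orc_pf_effect: 0.00
  rf_base: 0.60
  pf_base: 0.05
  elements:
    - label: RAP1
      start: -32
      end: -20
      consensus: ACACCCATACATT
      rf_effect: 0.00
      pf_effect: 0.80
    - label: YHP1
      start: 55
      end: 66
      consensus: TAATTGAATTGA
      rf_effect: 0.10
      pf_effect: 0.00

nonpartitioning:
  # An ARS422-like control locus: a strong ORC site and a 3' replication
  # element, but no partitioning element.
  length: 400
  upstream: 160
  orc_site: TTTTATGTTTAGTTTTA
  orc_rf_effect: 0.20
  orc_pf_effect: 0.00
  rf_base: 0.60
  pf_base: 0.05
  elements:
    - label: B2
      start: 60
      end: 80
      consensus: ACTTTTAGCAATTTTAGCAAT
      rf_effect: 0.10
      pf_effect: 0.00
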