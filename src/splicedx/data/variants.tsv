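# splicedx packaged study table v1
# 11 MYO5B noncanonical variants of uncertain significance plus 2 canonical-site
# positive controls, with per-tool precomputed prediction outputs, gnomAD-style
# genotype counts (hom/het/persons; '-' = not reported), minigene/blood-RNA
# outcomes and ACMG evidence assignments.
# Columns:
#   hgvs_c            HGVS c. description (join key after parse->format normalization)
#   role              study | positive_control
#   novel             1 = newly identified, 0 = from prior literature
#   location          printed region label (checked against the packaged transcript model)
#   hsf_verdict       Human Splicing Finder verdict phrase
#   spliceai          semicolon-separated channel:delta pairs; 'max:0' = no effect reported
#   varseak_class     varSEAK class 1-5
#   mt_verdict        MutationTaster verdict phrase
#   maxent_ref/alt    MaxEntScan splice-site scores, reference and variant allele
#   gnomad            hom/het/total persons, '-' if absent from the database
#   events            observed aberrant species, kind:region:size:side joined by '|'
#                     (size '.' for exon skipping = the whole exon); empty = normal splicing
#   normal_fraction   correctly spliced fraction by qPCR (1 = only normal splicing)
#   blood_rna         patient-derived RNA finding, free text ('' = not assayed)
#   original_evidence / removals  ACMG codes before reclassification and the codes
#                     explicitly dropped when folding in the functional result
#   notes             source discrepancies and other annotations
hgvs_c	role	novel	location	hsf_verdict	spliceai	varseak_class	mt_verdict	maxent_ref	maxent_alt	gnomad	events	normal_fraction	blood_rna	original_evidence	removals	notes
c.1669-35A>C	study	1	Intron 13	Alteration of the WT branch point may affect splicing	acceptor_loss:0.14	1	No abrogation of potential splice sites	6.33	6.33	-	partial_intron_retention:13:96:acceptor	0.17		PM2_P+PP3+PP4	PP3
c.455+8T>C	study	1	Intron 4	No significant impact on splicing signals	max:0	1	Donor increased	9.22	9.22	0/71/280946		1		PM2_P+PM3_P+PP3+PP4	PM2_P,PP3	higher East Asian subpopulation frequency (>0.001)
c.2415-6C>G	study	1	Intron 19	Alteration of the WT acceptor site, most probably affecting splicing	max:0	2	Acceptor gained	10.21	6.81	0/169/279700		1		PM2_P+PP3	PM2_P	higher East Asian subpopulation frequency (>0.001)
c.613-11G>A	study	1	Intron 5	Alteration of the WT acceptor site, most probably affecting splicing	acceptor_loss:0.84;acceptor_gain:0.99	5	Donor increased; Donor gained	9.06	3.19	-	intron_retention:5:9:acceptor	0	9 nt intron 5 retention plus normal transcript (patient and carrier mother); consistent with minigene	PM2_P+PP3+PP4
c.4221G>A/p.(=)	study	1	Exon 31	Alteration of the WT donor site, most probably affecting splicing	donor_loss:0.32	5	Alteration within used splice site, likely to disturb normal splicing	6.29	1.46	-	exon_skipping:31:.:donor	0.3		PM2_P+PM3+PP3+PP4
c.4852+11A>G	study	0	Intron 36	No significant impact on splicing signals	max:0	1	No abrogation of potential splice sites	8.89	8.89	-		1		PM2_P+PM3_P+PP4
c.2090+3A>T	study	0	Intron 17	Alteration of the WT donor site, most probably affecting splicing	donor_loss:0.85	5	Donor lost	8.63	0.49	-	intron_retention:17:185:donor	0		PM2_P+PM3_P+PP3+PP4
c.1322+5G>A	study	0	Intron 10	Alteration of the WT donor site, most probably affecting splicing	donor_loss:0.28	5	No abrogation of potential splice sites	6.03	-0.42	-	exon_internal_deletion:10:134:donor	0.2		PM2_P+PM3+PP3+PP4
c.2414+5G>T	study	0	Intron 19	Alteration of the WT donor site, most probably affecting splicing	donor_loss:0.67;donor_gain:0.42	5	No abrogation of potential splice sites	9.60	4.28	-	exon_internal_deletion:19:71:donor|exon_internal_deletion:19:27:donor	0		PM2_P+PM3+PP3+PP4		27-nt truncation is in-frame: 9 residues removed (a printed '12 amino acids' figure conflicts with 27/3 = 9; the arithmetic is followed)
c.2349A>G/p.(=)	study	0	Exon 19	Activation of a cryptic donor site, potential alteration of splicing	donor_loss:0.09;donor_gain:0.25	1	No abrogation of potential splice sites	9.60	9.60	0/1/249462	exon_internal_deletion:19:71:donor	0.35		PM2_P+PM3+PP3+PP4
c.3045+3A>T	study	0	Intron 22	Alteration of the WT donor site, most probably affecting splicing	donor_loss:0.52	5	Donor lost	9.55	5.42	-	exon_internal_deletion:22:125:donor|exon_internal_deletion:22:4:donor	0.1		PM2_P+PM3_P+PP3+PP4		WT fraction 0.10 (text) vs 0.15 (figure caption); text value stored, figure value carried here
c.3538-1G>A	positive_control	0	Intron 25							-		0				canonical acceptor-site control; aberrant splicing confirmed
c.839-1G>A	positive_control	0	Intron 6							-		0				canonical acceptor-site control; aberrant splicing confirmed
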