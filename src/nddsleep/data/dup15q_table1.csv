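age_months,sex,duplication_type,epilepsy,spike_wave_index,medications
105,F,isodicentric,no,<35%,Risperidone;Melatonin
23,F,isodicentric,no,<35%,
108,F,isodicentric,no,<35%,
18,M,interstitial,no,<35%,
35,M,isodicentric,no,<35%,
54,M,isodicentric,no,<35%,
68,F,isodicentric,yes,45-50%,Clobazam;Topiramate
137,M,isodicentric,yes,40-45%,Topiramate
73,F,interstitial,yes,<35%,Lamotrigine;Guanfacine
19,M,isodicentric,yes,35-40%,Vigabatrin;Prednisolone
57,F,isodicentric,yes,<35%,
9,F,isodicentric,yes,<35%,Levetiracetam;Phenobarbital
55,M,isodicentric,yes,65-70%,
108,M,isodicentric,yes,<35%,
156,M,isodicentric,yes,40-45%,
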