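# Accessions removed from every analysis regardless of contaminant
# frequency: human keratins, serum albumin, and trypsin (common sample-prep
# contaminants).  Edit freely; matching is on exact accession.
P04264
P35908
P13645
P35527
P04259
P02538
P08779
P02533
P19013
Q7Z794
P02768
P00761
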