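# Atomic mass constants used by lipidenum.
#
# monoisotopic.*  mass of the principal (most abundant) isotope, in Da,
#                 from the AME2012/CODATA evaluation as distributed in
#                 standard proteomics/metabolomics mass tables.
# average.*       IUPAC standard atomic weights (2021 conventional values), Da.
# electron        electron rest mass, Da (CODATA).
#
# Do not edit without bumping `version`: all computed masses in the test
# suite are frozen against these numbers.
version=monoisotopic:AME2012;average:IUPAC-2021;electron:CODATA-2018
electron=0.00054857990943
monoisotopic.H=1.00782503207
monoisotopic.C=12.0
monoisotopic.N=14.0030740048
monoisotopic.O=15.99491461956
monoisotopic.P=30.97376163
monoisotopic.Na=22.9897692809
monoisotopic.K=38.96370668
monoisotopic.Li=7.01600455
average.H=1.008
average.C=12.011
average.N=14.007
average.O=15.999
average.P=30.973761998
average.Na=22.98976928
average.K=39.0983
average.Li=6.94
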