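>lasso_cyclase_C_synthetic role=cyclase synthetic lasso cyclase (C-protein) exemplar, asparagine-synthase-like; stands in for the LarB/BAL72547.1 family
MDRCDVMVAMRTETEGEDQADGAHRMQALRSEYIRAALLLGVMMAFDSPMDLPPGDPDWG
RLASTSLVTVAMSDVEWDYAAAIGDDRTMCGKCLLLGLFWPLSQKRRQGWHAVALAAVLA
AIIRNQAIMAALLTTAPRRLADTCLGARTLSHEVERVGAIVEWSSSFQRREAEISPHTRF
GILPGATLGTPNLVRQSPRVFYHEFGYGAKWAFAVIDLKHVPRIVDPPGLSVVLFGSRRV
ALDSDGRGSGVAVACALRQGDGAVGFAAAPGTADPDDVGRHDMQGVLADRLALKQPLGAC
EIRDRSASRRSLVQHTSRGGFAKATTLTPALEATMDAGRGGVSVDARQWMVATKLRALLA
PAKPESQRPIIEVGARLDHVRLGDTTELVRKCSLGLLDFALLNVDTNISLGRATARNVNS
SVMLFPVLGVAKHHTLVIRGAHRSETVVALSPTEALFGSDAVYQVEDELLFSVDTDMIAL
SLMTGDRTSDAKRMLRYLNDDDWIYALMVAPLFGSMTPDPKGMGARSNAPPDITALSWTD
LSAPKVMLRYDDTDVAKWTFFMDWGGTLVRSGLRRLSVVKGGRGCIFPLGCKLCGACALE
HRLS
>leader_peptidase_B_synthetic role=peptidase synthetic leader peptidase (B-protein) exemplar, transglutaminase-like
MLRDGDEAATAVLSRLLASATVDEVTIGMRFEEALSAVGGSISIGDSTLAAYPTLSGLGV
ATGAWDANIHLLLFPLFDTESMRDPVRGQGLLAPLAEFVLAHIAASVAGKSPDVPTESSE
LQAAEYAFPLQRYGTAHDPPGS
>rre_E_synthetic role=rre synthetic RiPP recognition element (E-protein) exemplar
MPTLEMPLRAFRGGWCTAIIHGRLIVAQGNTDELALAHGDGDMDRGDQEVTGLSRELGLV
RVIQPWQRRWLAGDPVFRGGYSALKLWAWPRQ
>abc_transporter_D_synthetic role=transporter synthetic ABC transporter exemplar 1
MTVPENQWPVLFAGFGELRRFAFATLAMLSDPEVVKTLEYAGPARFRHKYMGMQVVNRGA
PHNAMELSAMKAETFVDLTIEGPEEQIYKVNNLIEVARKQSDEEWDNSFAAYLMIVDTAG
PYCAALLHMHPSSLAAQPEGDSIVVDWGSCSFAESQLIQLAVLRHAGEFVRQITMMGVPG
LRDYGIRALRVEVNIMASATEPAMGPGVAGETTLGYWPPGGRARSSESSLNERGEATVWA
VKTLFLSSVADLEAMHHKGRGLRWAVAKANGGNVMIMRSLLAGLRRAVRTQRTDEVAVSL
PVPTTLPRAKEQKPNVAA
>abc_transporter_F_synthetic role=transporter synthetic ABC transporter exemplar 2
MSMGSQVAGSATGAIDDTLFGATASGRHVDDSAEEPQNWPLPPAGPFEVPRVKWRPAEPV
GDLGLQDVSVRPGGDDLGGGINELLGTEREASRGMNRHHHEVVSPWLNGATAKWTVMYAD
IHAPWSAEEAYGGVYVNPLKPPADVTLGGDSMMMNDFPRCDETQVGLESEDKLWTAGERP
GDTMVYAMFQPVFGTYHGGTWTRHAPDMSGVVDPDGCAVLQADREFRAGAPKQTFVVDRY
GLRTVTMTDADLAEGSRQGLGAGWTAGGVWYDREIELLLPTALRSVQDQAVVYPTFLSDG
MDRLM
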