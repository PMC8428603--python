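# PSIPRED VFORMAT (synthetic)

   1 L C  0.780 0.110 0.110
   2 M C  0.846 0.077 0.077
   3 S C  0.929 0.035 0.035
   4 Y C  0.835 0.083 0.083
   5 A C  0.868 0.066 0.066
   6 D C  0.755 0.122 0.122
   7 T C  0.885 0.057 0.057
   8 W C  0.934 0.033 0.033
   9 F C  0.915 0.042 0.042
  10 H C  0.927 0.036 0.036
  11 V C  0.882 0.059 0.059
  12 K C  0.799 0.100 0.100
  13 G C  0.904 0.048 0.048
  14 T C  0.792 0.104 0.104
  15 G C  0.916 0.042 0.042
  16 K H  0.118 0.763 0.118
  17 P H  0.042 0.915 0.042
  18 M H  0.108 0.783 0.108
  19 C H  0.088 0.825 0.088
  20 A H  0.094 0.813 0.094
  21 V H  0.056 0.888 0.056
  22 S H  0.107 0.786 0.107
  23 T H  0.086 0.829 0.086
  24 M H  0.124 0.751 0.124
  25 T H  0.099 0.802 0.099
  26 H C  0.834 0.083 0.083
  27 L C  0.771 0.114 0.114
  28 S H  0.061 0.877 0.061
  29 D H  0.087 0.826 0.087
  30 H H  0.052 0.895 0.052
  31 D H  0.059 0.881 0.059
  32 L H  0.082 0.836 0.082
  33 Y H  0.038 0.923 0.038
  34 D H  0.062 0.876 0.062
  35 I H  0.044 0.912 0.044
  36 K H  0.091 0.818 0.091
  37 W H  0.071 0.859 0.071
  38 F H  0.105 0.789 0.105
  39 M H  0.026 0.949 0.026
  40 G H  0.100 0.799 0.100
  41 A H  0.099 0.801 0.099
  42 S H  0.117 0.765 0.117
  43 C C  0.802 0.099 0.099
  44 G C  0.903 0.048 0.048
  45 L C  0.890 0.055 0.055
  46 L C  0.776 0.112 0.112
  47 D C  0.825 0.088 0.088
  48 Y C  0.834 0.083 0.083
  49 R C  0.883 0.058 0.058
  50 Y C  0.841 0.080 0.080
  51 C C  0.867 0.067 0.067
  52 R C  0.918 0.041 0.041
  53 G C  0.895 0.052 0.052
  54 M C  0.823 0.089 0.089
  55 W C  0.840 0.080 0.080
  56 G C  0.824 0.088 0.088
  57 R C  0.772 0.114 0.114
  58 E C  0.791 0.104 0.104
  59 H C  0.807 0.096 0.096
  60 Y C  0.813 0.094 0.094
  61 K C  0.813 0.094 0.094
  62 M C  0.865 0.068 0.068
  63 G C  0.944 0.028 0.028
  64 D C  0.905 0.047 0.047
  65 K C  0.908 0.046 0.046
  66 P C  0.902 0.049 0.049
  67 L C  0.869 0.066 0.066
  68 S C  0.934 0.033 0.033
  69 I C  0.888 0.056 0.056
  70 P C  0.850 0.075 0.075
  71 S C  0.765 0.117 0.117
  72 W C  0.848 0.076 0.076
  73 K C  0.793 0.103 0.103
  74 A C  0.777 0.111 0.111
  75 R C  0.851 0.075 0.075
  76 M C  0.907 0.046 0.046
  77 V C  0.809 0.095 0.095
  78 L C  0.904 0.048 0.048
  79 I C  0.855 0.073 0.073
  80 C C  0.780 0.110 0.110
  81 L C  0.943 0.029 0.029
  82 P C  0.830 0.085 0.085
  83 S C  0.809 0.095 0.095
  84 V C  0.919 0.040 0.040
  85 F C  0.775 0.112 0.112
  86 N C  0.897 0.051 0.051
  87 T C  0.788 0.106 0.106
  88 G C  0.828 0.086 0.086
  89 H C  0.796 0.102 0.102
  90 T C  0.918 0.041 0.041
  91 N C  0.828 0.086 0.086
  92 M C  0.945 0.028 0.028
  93 Q C  0.875 0.062 0.062
  94 M C  0.889 0.055 0.055
  95 Y C  0.854 0.073 0.073
  96 S C  0.812 0.094 0.094
  97 C C  0.829 0.086 0.086
  98 D C  0.938 0.031 0.031
  99 M C  0.790 0.105 0.105
 100 T C  0.948 0.026 0.026
 101 C C  0.902 0.049 0.049
 102 Q C  0.822 0.089 0.089
 103 S C  0.878 0.061 0.061
 104 S C  0.826 0.087 0.087
 105 V H  0.087 0.826 0.087
 106 E H  0.075 0.851 0.075
 107 N H  0.123 0.753 0.123
 108 T H  0.076 0.849 0.076
 109 I H  0.028 0.944 0.028
 110 E H  0.096 0.807 0.096
 111 L H  0.050 0.900 0.050
 112 C H  0.081 0.839 0.081
 113 F H  0.104 0.792 0.104
 114 V H  0.034 0.931 0.034
 115 Q H  0.123 0.753 0.123
 116 V H  0.094 0.811 0.094
 117 T C  0.950 0.025 0.025
 118 V C  0.802 0.099 0.099
 119 H H  0.040 0.920 0.040
 120 L H  0.065 0.871 0.065
 121 P H  0.044 0.911 0.044
 122 G H  0.062 0.876 0.062
 123 W H  0.089 0.823 0.089
 124 A H  0.049 0.902 0.049
 125 T H  0.122 0.755 0.122
 126 P H  0.081 0.839 0.081
 127 G H  0.088 0.824 0.088
 128 R H  0.078 0.845 0.078
 129 K H  0.112 0.776 0.112
 130 T H  0.102 0.795 0.102
 131 Y H  0.069 0.862 0.069
 132 G C  0.828 0.086 0.086
 133 L C  0.908 0.046 0.046
 134 F C  0.871 0.065 0.065
 135 Q C  0.922 0.039 0.039
 136 P C  0.896 0.052 0.052
 137 T C  0.870 0.065 0.065
 138 T C  0.808 0.096 0.096
 139 Y C  0.907 0.046 0.046
 140 Y C  0.800 0.100 0.100
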